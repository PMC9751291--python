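# socpools

Soil organic carbon (SOC) storage in tropical agricultural soils is hard to
predict because the mechanisms that stabilise and destabilise carbon are not
resolved. `socpools` implements a complete analysis chain for attacking that
problem with laboratory incubations and soil-horizon property tables:

1. **Chamber flux processing** — flush-resample headspace CO2 records from
   sealed incubation bottles are converted to cumulative C-CO2 curves
   (µg C g⁻¹ dry soil) with the ideal gas law at SATP (298.15 K, 100 kPa).
2. **Multi-pool decay kinetics** — each curve is fitted with a two-pool
   first-order compartment model with series flow, feedback and respiration
   loss from both pools,

   dC/dt = I + A·C,  A = [[−k₁, α₁₂k₂], [α₂₁k₁, −k₂]],  C(0) = C_init·γ,

   with transfer coefficients fixed at α₂₁ = 0.85, α₁₂ = 0.15 and free
   parameters (γ₁, k₁, k₂): the fast-pool share and the fast/slow decay
   rates (day⁻¹). Fitting is two-step — Nelder–Mead, then adaptive
   random-walk Metropolis under uniform priors — and a sensitivity-based
   collinearity index screens which parameter sets an incubation curve can
   actually identify.
3. **Edaphic inference** — the fitted k₁, k₂ and measured SOC are linked to
   44 physicochemical soil predictors through a three-stage mixed-model
   chain (random intercept per soil pit): Spearman screening of
   intercept-only-model residuals (308 tests, Bonferroni α = 0.05/308 =
   0.000162, including climate-median half-sets), a global model, and
   all-subsets AICc selection with exclusion of highly correlated predictor
   pairs, reporting marginal/conditional R².
4. **Gradient clustering** — Ward's minimum-variance clustering on unscaled
   data summarises carbon responses and top predictors along depth
   (5 clusters) and rainfall (3 clusters, surface soils) gradients.
5. **Synthetic landscapes** — a ground-truthed generator emulates the
   20-pit / ~75-horizon study envelope (rainfall 306–1493 mm, SOC
   0.23–2.91 %, mean ≈ 1.16 %) so every stage is testable end to end
   without field data.

## Worked example

```python
import numpy as np
from socpools import (two_pool_spec, predict_cumulative_co2,
                      PoolDecayModel, FitConfig)
from socpools.curves import SAMPLING_DAYS, CumulativeCurve

# simulate an incubation curve from known kinetics and refit it
spec = two_pool_spec(gamma1=0.05, k1=0.2, k2=0.002, c_init=11600.0)
clean = predict_cumulative_co2(spec).values
rng = np.random.default_rng(0)
noisy = np.r_[0.0, clean[1:] * (1 + rng.normal(0, 0.01, 24))]
curve = CumulativeCurve("demo", SAMPLING_DAYS, noisy)

model = PoolDecayModel(curve, c_init=11600.0,
                       config=FitConfig(iterations=3000, burn_in=600, seed=1))
print(model.fit().summary())
```

```
Two-pool SOC decay model fit
  sample:            demo
  observations:      25
  initial C (ug/g):  11600.0
  SSR:               0.001691
  MCMC acceptance:   0.29
  param       estimate        2.5%       97.5%     ESS  unit
  gamma1      0.049946    0.046147    0.053731     273  -
  k1           0.20307     0.18473     0.22637     271  day^-1
  k2         0.0019952   0.0019786    0.002013     261  day^-1
```

The generating values (γ₁ = 0.05, k₁ = 0.2 day⁻¹, k₂ = 0.002 day⁻¹) sit
inside every 95 % credible interval: the fast pool holds ~5 % of the
initial carbon and turns over in days (1/k₁ ≈ 5 days), while the slow pool
turns over in years (1/k₂ ≈ 500 days), which is why 90-day incubations
constrain k₂ only through the late near-linear part of the curve.

The whole pipeline on a synthetic landscape:

```bash
socpools run-all --out runs/demo --seed 3
```

writes `horizon_table.csv`, `chambers.csv`, `curves.csv`, `kinetics.csv`,
`screen.csv`, `selection.csv`, cluster summaries, a manifest and a report of
the top models (ΔAICc ≤ 2) per carbon response.

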