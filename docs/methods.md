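# Methods

## Compartment model

Soil carbon is represented as n pools (n = 2 or 3) with first-order decay
rates k_i (day⁻¹), arranged in series with feedback: decayed carbon from
pool j is routed to an adjacent pool i with transfer coefficient α_{i,j},
and the unrouted remainder (1 − Σ_i α_{i,j}) is respired as CO2. The state
obeys dC/dt = I + A·C with A[i,i] = −k_i and A[i,j] = α_{i,j}k_j on the
permitted off-diagonals, and C(0) = C_init·γ. For incubations I = 0, so
cumulative respiration follows from mass balance:
respired(t) = total(0) − total(t). The fitted models are autonomous, so the
system is solved exactly through the eigendecomposition of A (with a
per-time matrix-exponential fallback if A is numerically defective); the
solution is verified in the test suite against an independent explicit
Euler integrator at dt = 10⁻³ day (agreement < 10⁻⁴ relative over 90 days)
and satisfies total + respired = C_init to 10⁻⁸ relative.

Units are µg C g⁻¹ dry soil and days throughout. Pool 1 is the fast pool,
pool 2 the slow pool, and the ordering k₁ > k₂ is enforced everywhere so
the labels cannot switch. The permitted transfer topology is
adjacent-pools-only (α₂₁, α₁₂, α₃₂, α₂₃); the two-pool model is exactly
the three-pool model with the third row/column removed (tested to 10⁻¹⁰).

## Chamber flux processing

Bottles (0.5 L nominal) holding 50 g of dry-equivalent soil are sealed,
sampled, flushed with air, resealed and resampled on the 25-event schedule
(days 0, 2, 4, …, 85, 90). The carbon accumulated in one sealed interval is
computed from the headspace concentration difference Δppm by the ideal gas
law at SATP, here fixed at 298.15 K and 100 kPa (the IUPAC convention):

    mass C (µg) = Δppm·10⁻⁶ · (P·V)/(R·T) · 12.011·10⁶.

Headspace volume is the chamber volume minus soil volume
(mass / (bulk density · 1000)) when a bulk density is supplied, else the
nominal chamber volume. Negative interval increments (measurement noise)
are clamped to zero with a warning by default because the fitted curves
must be non-decreasing; a raw mode preserves them for auditing. The day-0
sampling event contributes zero flux; it opens the first interval.

With the two-pool kinetics used throughout (k₂ of order 10⁻³ day⁻¹) and
this geometry, interval headspace rises for high-SOC soils reach several
percent CO2 — up to ~10 % over the longest 5-day intervals — which is
physically consistent (and is why the bottles are flushed at every event);
the gas law remains accurate in this range.

## Two-step kinetic calibration

Free parameters are (γ₁, k₁, k₂) with γ₂ = 1 − γ₁; the transfers are fixed
at α₂₁ = 0.85, α₁₂ = 0.15 (values from a fraction-based model of one of
the study sites). C_init is fixed at the sample's measured SOC converted to
µg C g⁻¹. Default bounds: γ₁ ∈ [10⁻⁴, 0.5], k₁ ∈ [10⁻⁴, 1],
k₂ ∈ [10⁻⁶, 0.1] day⁻¹, plus k₁ > k₂.

**Error model.** Gas-chromatograph concentration error is proportional, so
the default fitting residuals are relative: r_i = (pred_i − obs_i)/obs_i at
points with obs > 0. A plain additive mode is selectable
(`FitConfig(error_model="additive")`). This choice is what makes the
Bayesian machinery calibrated under multiplicative noise: with additive
(unweighted) residuals the posterior is measurably overconfident for k₂
(the late, large-valued points dominate the unweighted sum).

**Step 1 — simplex.** Nelder–Mead in (γ₁, log k₁, log k₂) coordinates with
bound/ordering violations penalised. The residual-sum surface has a local
optimum where the fast pool collapses into the slow one (γ₁ → 0, k₁ ≈ k₂),
so by default a 12-point multi-start grid over fast-pool share and
turnover is run and the best optimum polished with a fresh simplex.

**Step 2 — adaptive Metropolis.** Single-chain random-walk Metropolis with
uniform priors on the bounds. The residual variance is marginalised under
a Jeffreys prior, giving log-posterior ∝ −(n/2)·log SSR (a "simple" mode
instead fixes σ² at the simplex-fit mean squared error). The initial
proposal covariance is the scaled Gauss–Newton estimate
(2.4²/d)·σ²(JᵀJ)⁻¹ from finite-difference residual sensitivities at the
simplex optimum, re-estimated from the chain history every 200 iterations
during burn-in only (so the retained chain is Markovian). Defaults are
10,000 iterations with 2,000 burn-in; the validation studies below use
3,000/600, which the pilot calibration showed is sufficient for these
three-parameter posteriors. Acceptance rates outside [0.05, 0.6] are
flagged. Point estimates are posterior medians; intervals are equal-tailed
2.5/97.5 % quantiles; effective sample size uses the initial-positive-
sequence autocorrelation estimator. Chains are bit-reproducible for a
fixed seed.

Measured performance at the study conditions (25-day schedule, 1 %
multiplicative curve noise): on the identifiable part of the generating
grid γ₁ ∈ {0.02, 0.05, 0.1} × k₁ ∈ {0.05, 0.2} × k₂ ∈ {0.001, 0.005} the
median relative recovery error is ≈ 7 % for γ₁ and k₁ and < 1 % for k₂,
and 95 % credible intervals cover the generating values in ≥ 90/100
replicates per parameter. The grid corners with k₁/k₂ = 10 are excluded
from the recovery study *by the package's own identifiability screen*:
their collinearity index is 44–328, far above the ≤ 20 threshold, so the
attainable relative error along the sloppy parameter direction
(≈ index × noise) is several tens of percent for any estimator — these
are designs the collinearity analysis says not to fit, the same logic
that restricts the whole workflow to two-pool models.

**Identifiability.** The collinearity index of a parameter subset is
1/√(smallest eigenvalue of S̃ᵀS̃), where S̃ is the finite-difference
sensitivity matrix of the predicted curve with columns scaled to unit
norm. Orthonormal sensitivities give 1; linearly dependent or zero
sensitivities give ∞; index ≤ 20 is treated as identifiable (standard
practice). On the 25-day schedule the full three-pool free set
{γ₁, γ₂, k₁, k₂, k₃} scores orders of magnitude worse than the two-pool
{γ₁, k₁, k₂} set — the basis for analysing two-pool fits only.

## Mixed-model inference chain

All mixed models have a random intercept per pedon (soil pit) and are
fitted by maximum likelihood (not REML), since models with different fixed
effects are compared by information criteria. statsmodels' `MixedLM` is
the fitting engine.

**Screening.** For each response (SOC %, k₂, k₁) the intercept-only model's
conditional residuals (observed − fixed − predicted random effect) are
correlated (Spearman) with all 44 registry predictors on the full horizon
set and on six climate-median half-sets (rows at exactly the median go to
the "low" half): 44 × 7 = 308 tests, Bonferroni α = 0.05/308 = 0.000162.
Parses with fewer than 5 rows are skipped with a warning; the α divisor is
the number of tests actually run (308 with full data).

**Global model and selection.** The union of screened predictors across
the three responses, plus a-priori Roots × mineral-ratio interactions
(Roots:Fe_p/Al_p, Roots:Fe_c/Al_c, Roots:Si_p/Al_p, kept when both mains
survived screening), forms the global model. All subsets are enumerated
(guarded at 2²⁰ candidates), skipping any subset containing both members
of an exclusion pair — predictor pairs with |Spearman ρ| > 0.7 on the full
table — and admitting an interaction only alongside both main effects.
Candidates are ranked by AICc = −2logL + 2p + 2p(p+1)/(n−p−1), where p
counts fixed effects (with intercept) plus the two variance components;
models within 2 AICc points of the best form the reported top set.
Marginal and conditional R² follow the variance-partitioning convention:
var(Xβ̂) / (var(Xβ̂) + σ²_pedon + σ²_resid), with the pedon variance added
to the numerator for the conditional version. Missing cells are handled by
listwise deletion per fit, with n reported per model.

## Ward gradient clustering

Agglomerative clustering with Ward's minimum-variance criterion on squared
Euclidean distances: the merge cost is ΔSSE = |A||B|/(|A|+|B|)·‖mean_A −
mean_B‖², maintained by the Lance–Williams recurrence; ties are broken by
the lowest cluster-id pair so results are deterministic for a given row
order. The implementation is verified against an exhaustive agglomerator
that recomputes every candidate merge cost from raw cluster members, and
its partitions match `scipy.cluster.hierarchy` Ward linkage.

Clustering runs on *unscaled* data deliberately: depth (0–100 cm) and
rainfall (306–1493 mm) dominate the distances numerically, so horizons
group primarily along the chosen gradient with no weighting step (the test
suite documents that rescaling depth changes memberships). Depth profiles
use k = 5 on all horizons; rainfall uses k = 3 on surface horizons (the
shallowest per pit) with the pit's rainfall appended. Additional clusters
beyond these reduce within-cluster variance little (the variance-vs-k
curve is available via `within_cluster_variance`). Cluster summaries
report median, quartiles and a notched-boxplot 95 % CI of the median
(±1.58·IQR/√n), with clusters renumbered along the gradient.

## Synthetic landscape generator

The generator emulates the statistical structure the analysis assumes, not
pedological realism: 20 pits with climate drawn inside the study envelope
(rainfall 306–1493 mm from a right-skewed Beta, RH and temperature tied to
rainfall), 2–6 horizons per pit to 1 m (≈ 75 total), and all 44 registry
predictors as truncated normals/lognormals with depth trends (Roots,
WS_agg and the organo-metal ratios decline with depth), rainfall trends
(Clay and WS_agg rise, CEC falls) and cross-correlations induced by shared
latent weathering factors. Derived ratio columns are computed from their
base columns (consistent to 10⁻⁹) and texture sums to exactly 100.

Responses are generated from a known model: SOC (%) = 1.16 + Σ β_j·z_j +
pedon + ε over the four drivers {CEC, WS_agg, Fe_p/Al_p, Roots} with
effects (0.24, 0.19, 0.20, 0.25) % per SD, clipped to the 0.23–2.91 %
envelope; k₂ = 0.0028 + 0.0011·z(Roots) + pedon + ε day⁻¹; k₁ = 0.115 +
0.007·z(AEC) − 0.007·z(CEC) + pedon + ε day⁻¹. Variance components are
calibrated (once, by a large-sample run, then frozen) so the SOC model's
marginal R² is 0.78 and conditional R² 0.816, k₂'s marginal R² ≈ 0.55 and
k₁'s ≈ 0.08 — the scales the inference chain is meant to operate at.
Standardisation constants z_j are fixed population values, so the
generating coefficients are interpretable per SD.

Four predictors act as correlated proxies of the four SOC drivers
(WC_15kPa ↔ CEC, NWS_agg ↔ WS_agg, Fe_h/Al_h ↔ Fe_p/Al_p, Depth ↔ Roots)
at |ρ| ≈ 0.8 — strong enough that the |ρ| > 0.7 exclusion rule engages,
weak enough that the causal member is statistically distinguishable at
n ≈ 75. Incubation series are forward-simulated from each horizon's
(γ₁, k₁, k₂) and SOC through the compartment model and inverted through
the gas law to headspace ppm (0.5 L chamber, 50 g soil, ambient 415 ppm),
with multiplicative noise of CV 1 % per interval; the noise-free mode
round-trips through flux processing to < 10⁻⁶ µg g⁻¹. All draws flow from
a single mandatory seed; equal seeds give byte-identical outputs.

**What passing tests do and do not show.** The generator's linear response
models, factor-induced correlations and iid noise match the assumptions of
the inference chain by construction; success on synthetic data therefore
validates the machinery (fitting, screening, selection, clustering), not
the field applicability of those assumptions. Real horizon data bring
non-linear predictor–response relationships, depth-autocorrelated errors
and measurement artefacts the generator deliberately omits.

### Noise models and validation problem sizes

The chamber generator applies noise per sealed interval; summed into a
cumulative curve this is a random walk, under which no iid likelihood is
exactly calibrated. The calibration and coverage studies therefore apply
1 % iid multiplicative noise to the cumulative curve itself — the process
the proportional-error likelihood assumes — while the end-to-end pipeline
keeps the per-interval noise. Validation problem sizes: 27 recovery fits
over the identifiability-screened generating grid, 100 coverage
replicates, 50 landscapes each for term-set and R² recovery, 100 random
instances (n ≤ 10) for the Ward oracle; MCMC at 3,000/600 iterations in
these studies.

### The depth-gradient demonstration landscape

Strict monotonicity of the five depth-cluster medians of Roots, SOC and k₂
is *not* an expected property of the study-default landscape: root inputs
decay with a 22 cm e-folding, so true differences between clusters below
~50 cm are smaller than the sampling error of their medians, and SOC's
depth-independent drivers (CEC, WS_agg) can split shallow clusters
off-gradient (replacing the clustering with ideal depth-quantile bands
changes none of this). The gradient check therefore runs on a dedicated
demonstration configuration (`gradient_demo_config`: 100 pits, 60 cm root
e-folding, SOC weighted onto its depth-trended drivers, tighter response
noise) in which the variables genuinely decay through the full metre —
there a correct clustering must, and does, recover strictly monotone
profiles, while the study-default landscape is asserted to show the strong
surface-to-depth decline only.

## Known limitations

- The package analyses autonomous systems only: no time-varying inputs or
  rates, no pool counts above 3, no isotope tracers.
- Three-pool models are supported by the forward solver and collinearity
  screen, but the calibration path targets the two-pool model (the
  identifiable one on this design).
- The AICc parameter count includes the variance components; conventions
  differ across software, shifting all AICc values by a constant without
  affecting rankings.
- Spearman p-values use the large-sample t approximation; at n ≈ 37 per
  climate half-set this is standard but approximate.
- The all-subsets enumerator fits each candidate independently; above ~15
  global terms this is deliberately refused rather than approximated.
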