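"""Two-step calibration of pool models to cumulative respiration curves.

A :class:`PoolDecayModel` binds one cumulative C-CO2 curve (and the sample's
measured initial carbon) to a two-pool decay model with fixed transfer
coefficients (forward 0.85, feedback 0.15 by default).  ``fit()`` performs
the two-step estimation: a Nelder-Mead simplex search for a point estimate
of (gamma1, k1, k2), followed by adaptive random-walk Metropolis sampling of
the posterior under uniform priors on the parameter bounds and a Gaussian
likelihood whose residual variance is marginalised with a Jeffreys prior.
The result object carries point estimates (posterior medians), equal-tailed
credible intervals, the posterior draws and convergence diagnostics.

The module also provides the sensitivity-based collinearity index used to
decide how many parameters an incubation curve can identify: columns of the
finite-difference sensitivity matrix are scaled to unit norm and the index
is 1/sqrt of the smallest eigenvalue of their cross-product.  Larger values
mean a flatter objective along some parameter combination, i.e. a less
identifiable parameter set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .compartments import PoolModelSpec, predict_cumulative_co2, two_pool_spec
from .curves import SAMPLING_DAYS, CumulativeCurve

__all__ = [
    "FitConfig",
    "PoolDecayModel",
    "PoolDecayResults",
    "cost_ssr",
    "fit_neldermead",
    "fit_mcmc",
    "collinearity_index",
    "collinearity_index_from_matrix",
]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    # fast pool must turn over within the 90-day window; slow pool slower
    "gamma1": (1e-4, 0.5),
    "k1": (1e-4, 1.0),
    "k2": (1e-6, 0.1),
}


@dataclass
class FitConfig:
    """Settings for the two-step fit.

    ``free`` lists the free parameters (gamma2 = 1 - gamma1 is implied);
    ``alpha_forward``/``alpha_backward`` are the fixed transfer
    coefficients; ``bounds`` are uniform-prior bounds per parameter.  The
    ordering constraint k1 > k2 is always enforced so the labels "fast" and
    "slow" cannot switch during sampling.
    """

    free: tuple[str, ...] = ("gamma1", "k1", "k2")
    alpha_forward: float = 0.85
    alpha_backward: float = 0.15
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    iterations: int = 10_000
    burn_in: int = 2_000
    seed: int | None = None
    sigma_mode: str = "jeffreys"      # "jeffreys" | "simple"
    #: "proportional" matches the multiplicative measurement error of gas
    #: chromatography (relative residuals); "additive" is plain SSR
    error_model: str = "proportional"

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("chain shorter than burn-in")
        if self.sigma_mode not in ("jeffreys", "simple"):
            raise ValueError("sigma_mode must be 'jeffreys' or 'simple'")
        if self.error_model not in ("proportional", "additive"):
            raise ValueError("error_model must be 'proportional' or 'additive'")
        for name in self.free:
            if name not in self.bounds:
                raise ValueError(f"no bounds for free parameter {name}")
        lo, hi = self.bounds["gamma1"]
        if not (0 < lo < hi < 1):
            raise ValueError("gamma1 bounds must lie in (0, 1)")
        for kname in ("k1", "k2"):
            lo, _ = self.bounds[kname]
            if lo <= 0:
                raise ValueError(f"{kname} lower bound must be positive")


def _spec_from_params(params: Mapping[str, float], c_init: float,
                      config: FitConfig) -> PoolModelSpec:
    return two_pool_spec(
        gamma1=params["gamma1"], k1=params["k1"], k2=params["k2"],
        c_init=c_init, alpha_forward=config.alpha_forward,
        alpha_backward=config.alpha_backward)


def cost_ssr(spec: PoolModelSpec, curve: CumulativeCurve) -> float:
    """Sum of squared residuals between predicted and observed curves."""
    pred = predict_cumulative_co2(spec, curve.days)
    return float(np.sum((pred.values - curve.values) ** 2))


@dataclass
class PoolDecayResults:
    """Estimates from a two-step pool-model fit.

    ``params`` are the downstream point estimates: the Nelder-Mead optimum
    after step one, replaced by posterior medians after the MCMC step.
    """

    model: "PoolDecayModel"
    params: pd.Series
    cost: float
    posterior: pd.DataFrame | None = None
    acceptance_rate: float | None = None
    ess: pd.Series | None = None
    converged: bool = True

    @property
    def param_names(self) -> list[str]:
        return list(self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Equal-tailed credible intervals from the posterior draws."""
        if self.posterior is None:
            raise ValueError("no posterior draws; run the MCMC step")
        lo = self.posterior.quantile(alpha / 2)
        hi = self.posterior.quantile(1 - alpha / 2)
        return pd.DataFrame({"lower": lo, "upper": hi})

    def spec(self) -> PoolModelSpec:
        return _spec_from_params(self.params, self.model.c_init,
                                 self.model.config)

    def summary(self) -> str:
        lines = [
            "Two-pool SOC decay model fit",
            f"  sample:            {self.model.curve.sample_id}",
            f"  observations:      {len(self.model.curve)}",
            f"  initial C (ug/g):  {self.model.c_init:.1f}",
            f"  SSR:               {self.cost:.4g}",
        ]
        if self.acceptance_rate is not None:
            lines.append(f"  MCMC acceptance:   {self.acceptance_rate:.2f}")
        units = {"gamma1": "-", "k1": "day^-1", "k2": "day^-1"}
        header = f"  {'param':<8}{'estimate':>12}"
        ci = None
        if self.posterior is not None:
            ci = self.conf_int()
            header += f"{'2.5%':>12}{'97.5%':>12}"
            if self.ess is not None:
                header += f"{'ESS':>8}"
        header += "  unit"
        lines.append(header)
        for name in self.param_names:
            row = f"  {name:<8}{self.params[name]:>12.5g}"
            if ci is not None:
                row += f"{ci.loc[name, 'lower']:>12.5g}{ci.loc[name, 'upper']:>12.5g}"
                if self.ess is not None:
                    row += f"{self.ess[name]:>8.0f}"
            row += f"  {units.get(name, '')}"
            lines.append(row)
        return "\n".join(lines)


class PoolDecayModel:
    """Two-pool decay model bound to one observed cumulative curve.

    Parameters
    ----------
    curve : CumulativeCurve
        Observed cumulative C-CO2 (ug C g^-1 dry soil) on days in [0, 90].
    c_init : float
        Measured initial carbon of the sample (ug C g^-1), held fixed.
    config : FitConfig
        Free parameters, fixed transfers, bounds and MCMC settings.
    """

    def __init__(self, curve: CumulativeCurve, c_init: float,
                 config: FitConfig | None = None):
        self.curve = curve
        self.c_init = float(c_init)
        self.config = config or FitConfig()
        if self.c_init <= 0:
            raise ValueError("c_init must be positive")

    # -- objective ---------------------------------------------------------
    def _params_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.config.free, theta))

    def _in_bounds(self, theta: np.ndarray) -> bool:
        p = self._params_dict(theta)
        for name, value in p.items():
            lo, hi = self.config.bounds[name]
            if not (lo <= value <= hi):
                return False
        return p["k1"] > p["k2"]

    def _ssr(self, theta: np.ndarray) -> float:
        spec = _spec_from_params(self._params_dict(theta), self.c_init,
                                 self.config)
        return cost_ssr(spec, self.curve)

    def _residuals(self, theta: np.ndarray | Mapping[str, float]) -> np.ndarray:
        """Fitting residuals under the configured error model.

        Proportional (default): (pred - obs) / obs at points with obs > 0,
        matching multiplicative measurement error.  Additive: pred - obs at
        every point.
        """
        pred = self.predict(theta)
        obs = self.curve.values
        if self.config.error_model == "proportional":
            mask = obs > 0
            return (pred[mask] - obs[mask]) / obs[mask]
        return pred - obs

    def _objective(self, theta: np.ndarray) -> float:
        r = self._residuals(theta)
        return float(r @ r)

    def predict(self, theta: np.ndarray | Mapping[str, float]) -> np.ndarray:
        if not isinstance(theta, Mapping):
            theta = self._params_dict(np.asarray(theta, dtype=float))
        spec = _spec_from_params(theta, self.c_init, self.config)
        return predict_cumulative_co2(spec, self.curve.days).values

    # -- step 1: simplex ---------------------------------------------------
    def _default_starts(self) -> list[np.ndarray]:
        """Multi-start grid over the fast/slow regimes the bounds admit.

        The SSR surface has a local optimum where the fast pool collapses
        into the slow one (gamma1 -> 0, k1 ~ k2), so a single simplex run
        can miss a genuinely two-phase curve; a handful of starts spanning
        fast-pool share and turnover is cheap insurance.
        """
        starts = []
        for g1 in (0.02, 0.05, 0.15):
            for k1 in (0.05, 0.2):
                for k2 in (0.001, 0.005):
                    starts.append(np.array([g1, k1, k2]))
        return starts

    def fit_neldermead(self, start: Sequence[float] | None = None
                       ) -> PoolDecayResults:
        """Nelder-Mead minimisation of the SSR over the free parameters.

        The search runs in (gamma1, log k1, log k2) coordinates so the two
        rate scales are comparable; bound and ordering violations are
        penalised.  With no explicit start, a small multi-start grid is
        used and the best local optimum is polished by a restart.
        """
        cfg = self.config
        if start is not None:
            starts = [np.asarray(start, dtype=float)]
            if not self._in_bounds(starts[0]):
                raise ValueError("start point violates bounds or k1 > k2")
        else:
            starts = [s for s in self._default_starts() if self._in_bounds(s)]

        is_rate = np.array([n.startswith("k") for n in cfg.free])

        def to_theta(z: np.ndarray) -> np.ndarray:
            theta = z.copy()
            theta[is_rate] = np.exp(z[is_rate])
            return theta

        def objective(z: np.ndarray) -> float:
            theta = to_theta(z)
            if not self._in_bounds(theta):
                return 1e12
            return self._objective(theta)

        def run(theta0: np.ndarray, budget: int):
            z0 = theta0.copy()
            z0[is_rate] = np.log(theta0[is_rate])
            return scipy.optimize.minimize(
                objective, z0, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": budget,
                         "maxfev": budget})

        results = [run(s, 600) for s in starts]
        best = min(results, key=lambda r: r.fun)
        # polish the winner with a fresh simplex and a full budget
        polished = run(to_theta(best.x), 4000)
        if polished.fun <= best.fun:
            best = polished
        if not best.success:
            warnings.warn(
                f"{self.curve.sample_id}: Nelder-Mead did not converge "
                f"({best.message}); returning best point found", stacklevel=2)
        theta = to_theta(best.x)
        return PoolDecayResults(
            model=self, params=pd.Series(theta, index=list(cfg.free)),
            cost=float(best.fun), converged=bool(best.success))

    # -- step 2: adaptive Metropolis ----------------------------------------
    def _log_post(self, theta: np.ndarray, sigma2: float | None) -> float:
        if not self._in_bounds(theta):
            return -np.inf
        obj = self._objective(theta)
        n = self._residuals(theta).size
        if self.config.sigma_mode == "jeffreys":
            # residual variance marginalised under p(sigma^2) ~ 1/sigma^2
            return -0.5 * n * np.log(max(obj, 1e-300))
        return -0.5 * obj / sigma2

    def _proposal_covariance(self, theta: np.ndarray) -> np.ndarray:
        """FME-style initial proposal: scaled Gauss-Newton covariance
        sigma^2 (J'J)^-1 from finite-difference residual sensitivities at
        the simplex optimum."""
        p = theta.size
        base = self._residuals(theta)
        n = base.size
        J = np.empty((n, p))
        for i in range(p):
            h = max(abs(theta[i]), 1e-8) * 1e-5
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            J[:, i] = (self._residuals(up) - self._residuals(dn)) / (2 * h)
        sigma2 = max(self._objective(theta) / max(n - p, 1), 1e-12)
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.diag((0.01 * np.maximum(np.abs(theta), 1e-6)) ** 2)
        return (2.4 ** 2 / p) * cov

    def fit_mcmc(self, init: PoolDecayResults) -> PoolDecayResults:
        """Adaptive random-walk Metropolis around the simplex optimum.

        Single chain; the proposal covariance starts from the scaled
        Gauss-Newton estimate and is re-estimated from the chain history
        during burn-in (with a small jitter to keep it positive definite).
        Reproducible for a fixed ``config.seed``.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        theta = init.params.to_numpy(dtype=float).copy()
        p = theta.size
        n = self._residuals(theta).size
        sigma2 = max(init.cost / max(n - p, 1), 1e-12) \
            if cfg.sigma_mode == "simple" else None

        cov = self._proposal_covariance(theta)
        chol = np.linalg.cholesky(cov)
        logp = self._log_post(theta, sigma2)
        draws = np.empty((cfg.iterations, p))
        accepted = 0
        jitter = 1e-12 * np.eye(p)
        for it in range(cfg.iterations):
            prop = theta + chol @ rng.standard_normal(p)
            logp_prop = self._log_post(prop, sigma2)
            if np.log(rng.random()) < logp_prop - logp:
                theta, logp = prop, logp_prop
                accepted += 1
            draws[it] = theta
            # adapt during burn-in only, so the kept chain is Markovian
            if it < cfg.burn_in and it >= 200 and (it + 1) % 200 == 0:
                hist_cov = np.cov(draws[: it + 1].T)
                try:
                    chol = np.linalg.cholesky(
                        (2.4 ** 2 / p) * hist_cov + jitter)
                except np.linalg.LinAlgError:
                    pass

        rate = accepted / cfg.iterations
        if not 0.05 <= rate <= 0.6:
            warnings.warn(
                f"{self.curve.sample_id}: MCMC acceptance rate {rate:.3f} "
                "outside [0.05, 0.6]", stacklevel=2)
        kept = draws[cfg.burn_in:]
        posterior = pd.DataFrame(kept, columns=list(cfg.free))
        medians = posterior.median()
        return PoolDecayResults(
            model=self,
            params=medians,
            cost=self._objective(medians.to_numpy()),
            posterior=posterior,
            acceptance_rate=rate,
            ess=posterior.apply(_effective_sample_size),
            converged=init.converged and 0.05 <= rate <= 0.6,
        )

    def fit(self, method: str = "two-step",
            start: Sequence[float] | None = None) -> PoolDecayResults:
        """Fit the model. ``method`` is "two-step" (default) or "neldermead"."""
        point = self.fit_neldermead(start=start)
        if method == "neldermead":
            return point
        if method != "two-step":
            raise ValueError("method must be 'two-step' or 'neldermead'")
        return self.fit_mcmc(point)


def _effective_sample_size(x: pd.Series) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    v = x.to_numpy(dtype=float)
    v = v - v.mean()
    n = v.size
    if n < 4 or np.allclose(v, 0):
        return float(n)
    acf = np.correlate(v, v, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for t in range(1, n // 2):
        if acf[t] + acf[t + 1] < 0:  # pairwise positive-sequence cutoff
            break
        s += acf[t]
    return float(np.clip(n / (1 + 2 * s), 1, n))


# -- convenience wrappers matching the pipeline surface ---------------------

def fit_neldermead(curve: CumulativeCurve, c_init: float,
                   config: FitConfig | None = None,
                   start: Sequence[float] | None = None) -> PoolDecayResults:
    return PoolDecayModel(curve, c_init, config).fit_neldermead(start=start)


def fit_mcmc(curve: CumulativeCurve, c_init: float,
             init: PoolDecayResults,
             config: FitConfig | None = None) -> PoolDecayResults:
    return PoolDecayModel(curve, c_init, config or init.model.config
                          ).fit_mcmc(init)


# -- identifiability --------------------------------------------------------

def collinearity_index_from_matrix(S: np.ndarray) -> float:
    """Collinearity index of a sensitivity matrix.

    Columns are scaled to unit Euclidean norm; the index is
    ``1/sqrt(min eigenvalue of S~' S~)``.  Orthonormal columns give 1;
    linearly dependent columns give +inf; a zero column (a parameter the
    observations carry no information about) gives +inf.
    """
    S = np.asarray(S, dtype=float)
    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0):
        return float("inf")
    Sn = S / norms
    eigmin = float(np.linalg.eigvalsh(Sn.T @ Sn)[0])
    if eigmin <= 0:
        return float("inf")
    return 1.0 / np.sqrt(eigmin)


_PARAM_SETTERS = ("gamma1", "gamma2", "k1", "k2", "k3")


def _apply_free_params(spec: PoolModelSpec, values: Mapping[str, float]
                       ) -> PoolModelSpec:
    k = spec.k.copy()
    gamma = spec.gamma.copy()
    for name, val in values.items():
        if name == "gamma1":
            gamma[0] = val
        elif name == "gamma2":
            gamma[1] = val
        elif name.startswith("k"):
            k[int(name[1:]) - 1] = val
        else:
            raise ValueError(f"unknown parameter {name}")
    gamma[-1] = 1.0 - gamma[:-1].sum()   # last pool share is implied
    return replace(spec, k=k, gamma=gamma, _validated=False)


def collinearity_index(spec: PoolModelSpec, parameter_subset: Sequence[str],
                       sampling_days: Sequence[float] | None = None,
                       rel_step: float = 1e-4) -> float:
    """Identifiability of a parameter subset on a sampling design.

    Central finite-difference sensitivities of the predicted cumulative
    curve with respect to each named parameter (gamma1, gamma2, k1..k3)
    form the columns of the sensitivity matrix; see
    :func:`collinearity_index_from_matrix` for the index itself.
    """
    if len(parameter_subset) == 0:
        raise ValueError("parameter subset must be non-empty")
    days = SAMPLING_DAYS if sampling_days is None else np.asarray(
        sampling_days, dtype=float)
    base = {name: (spec.gamma[0] if name == "gamma1"
                   else spec.gamma[1] if name == "gamma2"
                   else spec.k[int(name[1:]) - 1])
            for name in parameter_subset}
    cols = []
    for name in parameter_subset:
        h = max(abs(base[name]), 1e-8) * rel_step
        up = _apply_free_params(spec, {**base, name: base[name] + h})
        dn = _apply_free_params(spec, {**base, name: base[name] - h})
        cu = predict_cumulative_co2(up, days).values
        cd = predict_cumulative_co2(dn, days).values
        cols.append((cu - cd) / (2 * h))
    return collinearity_index_from_matrix(np.column_stack(cols))
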