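"""Edaphic-predictor inference: residual screening and AICc model selection.

The chain links each carbon response (SOC %, slow decay rate k2, fast decay
rate k1) to soil physicochemical predictors in three stages, always with a
random intercept per pedon (soil pit):

1. an intercept-only linear mixed model per response; its conditional
   residuals (observed minus fixed-plus-random predictions) are screened
   against every candidate predictor by Spearman correlation, on the full
   horizon set and on the six half-sets obtained by splitting at the median
   of each climate variable (rainfall, relative humidity, temperature) —
   44 predictors x 7 parses = 308 tests per response, judged at the
   Bonferroni level 0.05/308;
2. the union of screened predictors across the three responses, plus
   a-priori root x mineral-ratio interactions, forms a global model;
3. all subsets of the global terms are fitted by maximum likelihood and
   ranked by AICc, skipping subsets that contain both members of a highly
   correlated predictor pair and any interaction without both main effects.

Mixed models are fitted with statsmodels' ``MixedLM``; variance explained is
summarised by the marginal R^2 (fixed effects) and conditional R^2 (fixed
plus random) of Nakagawa-style variance partitioning.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .columns import CLIMATE, PIT_COLUMN, PREDICTORS

__all__ = [
    "LMMFit",
    "ScreenResult",
    "SelectionTable",
    "fit_lmm",
    "screen_residuals",
    "build_global_model",
    "aicc",
    "select_models",
    "r2_mixed",
    "exclusion_pairs_from_correlation",
    "DEFAULT_INTERACTIONS",
]

#: a-priori root x mineral-ratio interaction candidates for the final model
DEFAULT_INTERACTIONS: tuple[tuple[str, str], ...] = (
    ("Roots", "Fe_p/Al_p"),
    ("Roots", "Fe_c/Al_c"),
    ("Roots", "Si_p/Al_p"),
)


@dataclass
class LMMFit:
    """A fitted random-intercept mixed model (ML).

    ``n_params`` counts fixed effects (incl. intercept) plus the two
    variance components (pedon intercept, residual), as used in AICc.
    """

    response: str
    fixed_terms: tuple[str, ...]
    fe_params: pd.Series
    var_pedon: float
    var_resid: float
    loglik: float
    n_obs: int
    n_groups: int
    fitted_fixed: pd.Series          # X beta, indexed like the used rows
    conditional_residuals: pd.Series  # y - (X beta + random intercept)
    singular: bool = False

    @property
    def n_params(self) -> int:
        return len(self.fe_params) + 2


def _design(table: pd.DataFrame, response: str,
            fixed_terms: Sequence[str]) -> pd.DataFrame:
    cols = [PIT_COLUMN, response, *fixed_terms]
    rows = table[cols].dropna()
    if rows.empty:
        raise ValueError(f"no complete rows for response {response}")
    return rows


def _interaction_column(table: pd.DataFrame, term: str) -> pd.Series:
    a, b = term.split(":")
    return table[a] * table[b]


def _with_interactions(table: pd.DataFrame,
                       terms: Sequence[str]) -> pd.DataFrame:
    out = table.copy()
    for t in terms:
        if ":" in t and t not in out.columns:
            out[t] = _interaction_column(out, t)
    return out


def fit_lmm(table: pd.DataFrame, response: str,
            fixed_terms: Sequence[str] = ()) -> LMMFit:
    """Fit a random-intercept LMM (grouping = pedon) by maximum likelihood.

    ``fixed_terms`` may include interaction terms written ``"A:B"`` (the
    elementwise product of the two named columns).  An empty term list is
    the intercept-only model, i.e. a random-effects ANOVA.  A singular fit
    (zero pedon variance) is flagged but retained.  Rows with a missing
    response or predictor are dropped (listwise deletion).
    """
    fixed_terms = tuple(fixed_terms)
    work = _with_interactions(table, fixed_terms)
    rows = _design(work, response, fixed_terms)
    y = rows[response].to_numpy(dtype=float)
    groups = rows[PIT_COLUMN].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ValueError("grouping factor needs at least 2 levels")
    exog = sm.add_constant(
        rows[list(fixed_terms)].to_numpy(dtype=float), has_constant="add")
    names = ["Intercept", *fixed_terms]

    if np.ptp(y) == 0:  # constant response: degenerate but well-defined
        fe = pd.Series(np.r_[y[0], np.zeros(len(fixed_terms))], index=names)
        zeros = pd.Series(np.zeros(len(rows)), index=rows.index)
        return LMMFit(response, fixed_terms, fe, 0.0, 0.0,
                      loglik=np.inf, n_obs=len(rows), n_groups=n_groups,
                      fitted_fixed=pd.Series(y, index=rows.index),
                      conditional_residuals=zeros, singular=True)

    model = MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    fe = pd.Series(res.fe_params, index=names)
    var_pedon = float(np.squeeze(res.cov_re))
    var_resid = float(res.scale)
    fitted_fixed = exog @ fe.to_numpy()
    re = res.random_effects
    re_by_row = np.array([float(np.squeeze(re[g].iloc[0]))
                          if len(re[g]) else 0.0 for g in groups])
    cond_resid = y - (fitted_fixed + re_by_row)
    return LMMFit(
        response=response,
        fixed_terms=fixed_terms,
        fe_params=fe,
        var_pedon=var_pedon,
        var_resid=var_resid,
        loglik=float(res.llf),
        n_obs=len(rows),
        n_groups=n_groups,
        fitted_fixed=pd.Series(fitted_fixed, index=rows.index),
        conditional_residuals=pd.Series(cond_resid, index=rows.index),
        singular=var_pedon <= 1e-10 * max(var_resid, 1e-300),
    )


# -- stage 1: residual screening -------------------------------------------

@dataclass
class ScreenResult:
    """Spearman screen of intercept-only residuals against predictors."""

    response: str
    table: pd.DataFrame     # predictor, parse, n, rho, p, significant
    n_tests: int
    alpha: float

    def significant_predictors(self) -> list[str]:
        sig = self.table.loc[self.table["significant"], "predictor"]
        return sorted(sig.unique())


def _parses(table: pd.DataFrame) -> list[tuple[str, pd.Index]]:
    """The 7 row subsets: full set + low/high halves of each climate
    variable.  Rows at exactly the median go to the low half."""
    names = {"Rainfall": "rainfall", "RH": "humidity",
             "Temperature": "temperature"}
    out = [("all", table.index)]
    for var in CLIMATE:
        med = table[var].median()
        low = table.index[table[var] <= med]
        high = table.index[table[var] > med]
        name = names.get(var, var.lower())
        out.append((f"{name}-low", low))
        out.append((f"{name}-high", high))
    return out


def screen_residuals(table: pd.DataFrame, response: str,
                     predictors: Sequence[str] = tuple(PREDICTORS),
                     alpha_total: float = 0.05,
                     min_rows: int = 5) -> ScreenResult:
    """Screen every predictor x parse for correlation with the conditional
    residuals of the intercept-only LMM of ``response``.

    With the full 44-predictor registry and all 7 parses this performs 308
    tests, so the Bonferroni level is 0.05/308 = 0.000162.
    """
    base = fit_lmm(table, response, fixed_terms=())
    resid = base.conditional_residuals
    rows = []
    n_tests = 0
    for parse_name, idx in _parses(table.loc[resid.index]):
        if len(idx) < min_rows:
            warnings.warn(f"parse {parse_name} has <{min_rows} rows; skipped",
                          stacklevel=2)
            continue
        r = resid.loc[idx]
        for pred in predictors:
            x = table.loc[idx, pred]
            ok = r.notna() & x.notna()
            if ok.sum() < min_rows:
                warnings.warn(
                    f"parse {parse_name}, predictor {pred}: <{min_rows} "
                    "complete rows; skipped", stacklevel=2)
                continue
            rho, p = scipy.stats.spearmanr(x[ok], r[ok])
            rows.append({"predictor": pred, "parse": parse_name,
                         "n": int(ok.sum()), "rho": rho, "p": p})
            n_tests += 1
    if n_tests == 0:
        raise ValueError("no screening tests could be run")
    alpha = alpha_total / n_tests
    frame = pd.DataFrame(rows)
    frame["significant"] = frame["p"] < alpha
    return ScreenResult(response=response, table=frame,
                        n_tests=n_tests, alpha=alpha)


# -- stage 2: global model --------------------------------------------------

@dataclass
class GlobalModel:
    terms: list[str]
    interactions: list[tuple[str, str]] = field(default_factory=list)


def build_global_model(
    screens: Iterable[ScreenResult],
    interactions: Sequence[tuple[str, str]] = DEFAULT_INTERACTIONS,
) -> GlobalModel:
    """Union of screened predictors across responses, plus the root-mineral
    interaction candidates whose main effects both survived the screen."""
    union: set[str] = set()
    for sc in screens:
        union |= set(sc.significant_predictors())
    if not union:
        raise ValueError("no predictor passed the residual screen")
    terms = sorted(union)
    keep = [(a, b) for a, b in interactions if a in union and b in union]
    return GlobalModel(terms=terms, interactions=keep)


# -- stage 3: AICc all-subsets selection ------------------------------------

def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample Akaike criterion:
    AICc = -2 logL + 2p + 2p(p+1)/(n-p-1)."""
    denom = n_obs - n_params - 1
    if denom <= 0:
        raise ValueError("n_obs must exceed n_params + 1")
    return -2.0 * loglik + 2.0 * n_params + 2.0 * n_params * (n_params + 1) / denom


def r2_mixed(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional R^2 by variance partitioning.

    marginal = var(X beta) / (var(X beta) + var_pedon + var_resid);
    conditional adds the pedon variance to the numerator.
    """
    var_f = float(np.var(fit.fitted_fixed.to_numpy(), ddof=0))
    total = var_f + fit.var_pedon + fit.var_resid
    if total <= 0:
        raise ValueError("zero total variance")
    return var_f / total, (var_f + fit.var_pedon) / total


def exclusion_pairs_from_correlation(
    table: pd.DataFrame, terms: Sequence[str], threshold: float = 0.7
) -> list[tuple[str, str]]:
    """Predictor pairs whose |Spearman rho| on the full table exceeds the
    threshold; such pairs never co-occur in a candidate model."""
    pairs = []
    for a, b in itertools.combinations(terms, 2):
        ok = table[a].notna() & table[b].notna()
        if ok.sum() < 3:
            continue
        rho, _ = scipy.stats.spearmanr(table.loc[ok, a], table.loc[ok, b])
        if abs(rho) > threshold:
            pairs.append((a, b))
    return pairs


@dataclass
class SelectionTable:
    """Candidate mixed models ranked by AICc."""

    response: str
    table: pd.DataFrame   # terms, n_terms, n_obs, loglik, aicc, delta_aicc, r2m, r2c

    def top(self, delta: float = 2.0) -> pd.DataFrame:
        """Models statistically indistinguishable from the best
        (delta AICc <= 2 by default)."""
        return self.table[self.table["delta_aicc"] <= delta]

    def best_terms(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["terms"])


def select_models(
    table: pd.DataFrame,
    response: str,
    global_terms: Sequence[str],
    interactions: Sequence[tuple[str, str]] = (),
    exclusion_pairs: Sequence[tuple[str, str]] = (),
    max_candidates: int = 2 ** 20,
    include_null: bool = True,
) -> SelectionTable:
    """All-subsets AICc selection over the global term list.

    Every subset of main-effect terms is fitted by ML (with the pedon
    random intercept), skipping subsets containing both members of an
    exclusion pair; interaction terms enter only in subsets that contain
    both of their main effects (marginality).  Candidates are ranked by
    AICc; the "top set" of practically equivalent models is
    ``SelectionTable.top()``.
    """
    global_terms = list(global_terms)
    excl = [frozenset(p) for p in exclusion_pairs]
    n_cand = 2 ** (len(global_terms) + len(interactions))
    if n_cand > max_candidates:
        raise ValueError(
            f"{n_cand} candidate subsets exceed the {max_candidates} guard; "
            "reduce the global model or raise max_candidates explicitly")

    records = []
    for r in range(0 if include_null else 1, len(global_terms) + 1):
        for mains in itertools.combinations(global_terms, r):
            mset = set(mains)
            if any(pair <= mset for pair in excl):
                continue
            applicable = [(a, b) for a, b in interactions
                          if a in mset and b in mset]
            for ir in range(len(applicable) + 1):
                for inters in itertools.combinations(applicable, ir):
                    terms = list(mains) + [f"{a}:{b}" for a, b in inters]
                    fit = fit_lmm(table, response, terms)
                    r2m, r2c = r2_mixed(fit)
                    records.append({
                        "terms": tuple(terms),
                        "n_terms": len(terms),
                        "n_obs": fit.n_obs,
                        "loglik": fit.loglik,
                        "aicc": aicc(fit.loglik, fit.n_params, fit.n_obs),
                        "r2m": r2m,
                        "r2c": r2c,
                    })
    frame = pd.DataFrame(records).sort_values(
        "aicc", kind="mergesort").reset_index(drop=True)
    frame["delta_aicc"] = frame["aicc"] - frame["aicc"].iloc[0]
    return SelectionTable(response=response, table=frame)
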