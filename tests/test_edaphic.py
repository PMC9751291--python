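import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from socpools.columns import PREDICTORS
from socpools.edaphic import (LMMFit, ScreenResult, aicc, build_global_model,
                              exclusion_pairs_from_correlation, fit_lmm,
                              r2_mixed, screen_residuals, select_models)


def grouped_frame(rng, n_groups=20, per_group=4, pedon_sd=1.0, resid_sd=1.0,
                  beta=None):
    """Random-intercept data with optional fixed effects."""
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, pedon_sd)
        for _ in range(per_group):
            x1, x2 = rng.normal(size=2)
            y = u + rng.normal(0, resid_sd)
            if beta is not None:
                y += beta[0] * x1 + beta[1] * x2
            rows.append({"pit_id": f"g{g}", "y": y, "x1": x1, "x2": x2})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_variance_component_recovery(self):
        df = grouped_frame(np.random.default_rng(0))
        fit = fit_lmm(df, "y")
        assert fit.var_pedon == pytest.approx(1.0, rel=0.5)
        assert fit.var_resid == pytest.approx(1.0, rel=0.5)
        assert fit.fixed_terms == ()

    def test_constant_response_degenerates_cleanly(self, rng):
        df = grouped_frame(rng)
        df["y"] = 3.0
        fit = fit_lmm(df, "y")
        assert fit.var_pedon == 0.0 and fit.var_resid == 0.0
        assert np.all(fit.conditional_residuals == 0)

    def test_conditional_residuals_remove_group_structure(self, rng):
        df = grouped_frame(rng, pedon_sd=3.0, resid_sd=0.5)
        fit = fit_lmm(df, "y")
        marginal = df["y"] - fit.fe_params["Intercept"]
        assert fit.conditional_residuals.var() < marginal.var()
        # per-group means of conditional residuals shrink towards zero
        by_group = fit.conditional_residuals.groupby(df["pit_id"]).mean()
        assert by_group.abs().max() < marginal.groupby(df["pit_id"]).mean().abs().max()

    def test_fixed_effect_estimates(self, rng):
        df = grouped_frame(rng, beta=(2.0, -1.0), resid_sd=0.3)
        fit = fit_lmm(df, "y", ["x1", "x2"])
        assert fit.fe_params["x1"] == pytest.approx(2.0, abs=0.2)
        assert fit.fe_params["x2"] == pytest.approx(-1.0, abs=0.2)
        assert fit.n_params == 5  # 3 fixed + 2 variance components

    def test_single_group_rejected(self, rng):
        df = grouped_frame(rng, n_groups=1)
        with pytest.raises(ValueError, match="2 levels"):
            fit_lmm(df, "y")


class TestAicc:
    def test_printed_arithmetic_example(self):
        # n=75, p=6, logL=0: 12 + 84/68
        assert aicc(0.0, 6, 75) == pytest.approx(12 + 84 / 68)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 4, 10**9) == pytest.approx(20 + 8, abs=1e-6)

    def test_denominator_guard(self):
        with pytest.raises(ValueError):
            aicc(0.0, 10, 11)

    @pytest.mark.parametrize("ll,p,n", [(-3.2, 2, 12), (-100.0, 7, 40),
                                        (5.5, 3, 9)])
    def test_matches_direct_formula(self, ll, p, n):
        assert aicc(ll, p, n) == pytest.approx(
            -2 * ll + 2 * p + 2 * p * (p + 1) / (n - p - 1))


class TestScreen:
    def test_full_registry_runs_308_tests(self, landscape):
        table, _ = landscape
        sc = screen_residuals(table, "SOC")
        assert sc.n_tests == 308
        assert sc.alpha == pytest.approx(0.05 / 308)
        assert f"{sc.alpha:.3g}" == "0.000162"
        assert set(sc.table["parse"]) == {
            "all", "rainfall-low", "rainfall-high", "humidity-low",
            "humidity-high", "temperature-low", "temperature-high"}

    def test_monotone_predictor_gives_rho_one(self, rng):
        df = grouped_frame(rng, n_groups=6, per_group=5)
        # predictor built as a strictly monotone transform of the
        # intercept-only conditional residuals themselves
        resid = fit_lmm(df, "y").conditional_residuals
        df["p"] = np.exp(resid.rank())
        df["Rainfall"] = 500.0 + df["p"]
        df["RH"] = 75.0
        df["Temperature"] = 24.0
        sc = screen_residuals(df, "y", predictors=["p"])
        row = sc.table[(sc.table["parse"] == "all")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_spearman_matches_midrank_oracle(self, landscape):
        table, _ = landscape
        fit = fit_lmm(table, "SOC")
        resid = fit.conditional_residuals
        x = table.loc[resid.index, "Clay"]
        # direct midrank-based computation: Pearson correlation of ranks
        rx = pd.Series(x).rank().to_numpy()
        rr = pd.Series(resid).rank().to_numpy()
        oracle = np.corrcoef(rx, rr)[0, 1]
        sc = screen_residuals(table, "SOC", predictors=["Clay"])
        got = sc.table[sc.table["parse"] == "all"].iloc[0]["rho"]
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_permuted_predictors_lose_significance(self, landscape):
        table, _ = landscape
        perm = table.copy()
        rng = np.random.default_rng(123)
        for col in PREDICTORS:
            perm[col] = rng.permutation(perm[col].to_numpy())
        sc = screen_residuals(perm, "SOC")
        # Bonferroni at 0.05/308 leaves no signal after permutation
        assert not sc.table["significant"].any()


class TestGlobalModel:
    @staticmethod
    def fake_screen(response, predictors):
        frame = pd.DataFrame({
            "predictor": predictors, "parse": "all",
            "n": 75, "rho": 0.9, "p": 1e-9, "significant": True})
        return ScreenResult(response, frame, 308, 0.05 / 308)

    def test_union_of_disjoint_sets(self):
        screens = [self.fake_screen("SOC", ["A"]),
                   self.fake_screen("k2", ["B"]),
                   self.fake_screen("k1", ["C"])]
        gm = build_global_model(screens, interactions=())
        assert gm.terms == ["A", "B", "C"]

    def test_interactions_require_screened_mains(self):
        screens = [self.fake_screen("SOC", ["Roots", "Fe_p/Al_p"])]
        gm = build_global_model(
            screens, interactions=(("Roots", "Fe_p/Al_p"),
                                   ("Roots", "Fe_c/Al_c")))
        assert gm.interactions == [("Roots", "Fe_p/Al_p")]

    def test_empty_screen_rejected(self):
        sc = ScreenResult("SOC", pd.DataFrame(
            {"predictor": ["A"], "parse": ["all"], "n": [75],
             "rho": [0.1], "p": [0.5], "significant": [False]}),
            308, 0.05 / 308)
        with pytest.raises(ValueError):
            build_global_model([sc])


class TestSelection:
    def test_candidate_sets_match_bruteforce_enumerator(self, rng):
        df = grouped_frame(rng, beta=(1.0, 0.0))
        df["x3"] = rng.normal(size=len(df))
        terms = ["x1", "x2", "x3"]
        interactions = [("x1", "x2")]
        exclusion = [("x2", "x3")]
        sel = select_models(df, "y", terms, interactions=interactions,
                            exclusion_pairs=exclusion)
        got = {frozenset(t) for t in sel.table["terms"]}
        expected = set()
        for r in range(4):
            for mains in itertools.combinations(terms, r):
                if {"x2", "x3"} <= set(mains):
                    continue
                expected.add(frozenset(mains))
                if {"x1", "x2"} <= set(mains):
                    expected.add(frozenset(list(mains) + ["x1:x2"]))
        assert got == expected

    def test_exclusion_pair_never_cooccurs(self, rng):
        df = grouped_frame(rng, beta=(1.0, 1.0))
        sel = select_models(df, "y", ["x1", "x2"],
                            exclusion_pairs=[("x1", "x2")])
        for t in sel.table["terms"]:
            assert not {"x1", "x2"} <= set(t)

    def test_strong_single_effect_selected(self, rng):
        df = grouped_frame(rng, beta=(3.0, 0.0), resid_sd=0.5)
        df["x3"] = rng.normal(size=len(df))
        sel = select_models(df, "y", ["x1", "x2", "x3"])
        assert "x1" in sel.best_terms()
        assert sel.table["delta_aicc"].iloc[0] == 0.0
        assert (sel.table["delta_aicc"] >= 0).all()

    def test_ranking_invariant_under_rescaling(self, rng):
        df = grouped_frame(rng, beta=(1.5, 0.3))
        sel1 = select_models(df, "y", ["x1", "x2"])
        df2 = df.copy()
        df2["y"] = df2["y"] * 10.0
        sel2 = select_models(df2, "y", ["x1", "x2"])
        assert list(sel1.table["terms"]) == list(sel2.table["terms"])
        shift = sel2.table["aicc"] - sel1.table["aicc"]
        np.testing.assert_allclose(shift, shift.iloc[0], atol=1e-4)

    def test_candidate_guard_refuses_huge_enumerations(self, rng):
        df = grouped_frame(rng)
        with pytest.raises(ValueError, match="guard"):
            select_models(df, "y", [f"t{i}" for i in range(25)],
                          max_candidates=2 ** 20)

    def test_exclusion_pairs_found_by_correlation(self, landscape):
        table, _ = landscape
        pairs = exclusion_pairs_from_correlation(
            table, ["CEC", "WC_15kPa", "Roots", "Depth"])
        assert ("CEC", "WC_15kPa") in pairs
        assert ("Roots", "Depth") in pairs
        assert ("CEC", "Roots") not in pairs


class TestR2Mixed:
    def test_intercept_only_marginal_is_zero(self, rng):
        fit = fit_lmm(grouped_frame(rng), "y")
        r2m, r2c = r2_mixed(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c >= r2m

    def test_pure_fixed_fit_reaches_one(self):
        fitted = pd.Series([1.0, 2.0, 3.0])
        fit = LMMFit(response="y", fixed_terms=("x",),
                     fe_params=pd.Series({"Intercept": 0.0, "x": 1.0}),
                     var_pedon=0.0, var_resid=0.0, loglik=0.0, n_obs=3,
                     n_groups=2, fitted_fixed=fitted,
                     conditional_residuals=pd.Series(np.zeros(3)))
        assert r2_mixed(fit) == (1.0, 1.0)

    def test_conditional_never_below_marginal(self, rng):
        for beta in [(0.0, 0.0), (1.0, -0.5)]:
            fit = fit_lmm(grouped_frame(rng, beta=beta), "y",
                          ["x1", "x2"])
            r2m, r2c = r2_mixed(fit)
            assert 0.0 <= r2m <= r2c <= 1.0
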