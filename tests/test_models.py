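"""Model-layer correctness: allometry OLS, candidate enumeration, the ML
mixed-model fit against brute-force likelihood oracles, AICc/weight
closed forms, the Nakagawa variance decomposition, and random-effect
diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sizeclines import models, workflow
from sizeclines.models import ModelSpec
from ._oracles import crossed_lmm_ml_oracle, ols_line


class TestAllometry:
    def test_exact_cube_law(self):
        L = np.array([70, 80, 90, 100, 110], dtype=float)
        df = pd.DataFrame({"hb_length": L, "body_mass": 2.5e-5 * L**3})
        fit = models.fit_allometry(df)
        assert fit.slope == pytest.approx(3.0, abs=1e-10)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_independent_response_near_zero_r2(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"hb_length": rng.uniform(70, 110, 5000),
                           "body_mass": rng.uniform(15, 25, 5000)})
        fit = models.fit_allometry(df)
        assert abs(fit.r2_adj) < 0.01

    def test_five_pair_fixture_matches_normal_equations(self):
        pairs = [(72.0, 14.1), (81.0, 17.9), (88.0, 19.5), (95.0, 23.8),
                 (104.0, 28.2)]
        df = pd.DataFrame(pairs, columns=["hb_length", "body_mass"])
        fit = models.fit_allometry(df)
        slope, intercept = ols_line(np.log(df["hb_length"]),
                                    np.log(df["body_mass"]))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_nonpositive_trait_rejected(self):
        df = pd.DataFrame({"hb_length": [80.0, -5.0, 90.0],
                           "body_mass": [18.0, 20.0, 22.0]})
        with pytest.raises(ValueError, match="positive"):
            models.fit_allometry(df)


class TestEnumeration:
    def test_all_subsets_of_five(self):
        specs = models.enumerate_candidates("body_mass", "spatial")
        assert len(specs) == 32
        assert any(s.fixed == () for s in specs)  # intercept-only included

    def test_all_subsets_of_six_temporal(self):
        specs = models.enumerate_candidates("body_mass", "temporal")
        assert len(specs) == 64

    def test_explicit_passthrough(self):
        explicit = [("MAT",), ("MAT", "sex"), ()]
        specs = models.enumerate_candidates("body_mass", "spatial",
                                            explicit=explicit)
        assert [s.fixed for s in specs] == [("MAT",), ("MAT", "sex"), ()]

    def test_spatial_rejects_decade(self):
        with pytest.raises(ValueError):
            ModelSpec("body_mass", ("decade",), "spatial")


class TestAicc:
    def test_arithmetic_example(self):
        assert models.aicc(-47.0, 3, 100) == pytest.approx(100.25)
        assert -2 * -47.0 + 2 * 3 == 100.0

    def test_limit_to_aic(self):
        k, ll = 4, -100.0
        assert models.aicc(ll, k, 10**7) == pytest.approx(-2 * ll + 2 * k,
                                                          abs=1e-4)

    def test_minimal_n(self):
        k = 3
        assert models.aicc(0.0, k, k + 2) == pytest.approx(2 * k + 2 * k * (k + 1))

    def test_undefined_below_minimal_n(self):
        with pytest.raises(ValueError):
            models.aicc(0.0, 3, 4)

    @given(ll=st.floats(-1e4, 0), k=st.integers(1, 10), n=st.integers(12, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_aicc_dominates_aic(self, ll, k, n):
        assert models.aicc(ll, k, n) >= -2 * ll + 2 * k


# 9-row crossed fixture with an interior ML optimum (clear group effects)
CROSSED_FIXTURE = pd.DataFrame({
    "ecoregion": list("AAABBBCCC"),
    "source": list("STUSTUSTU"),
    "body_mass": [6.65, 7.18, 8.98, 9.97, 9.72, 10.95, 11.26, 12.24, 13.29],
})


class TestLmmFit:
    def test_crossed_ml_matches_brute_force_oracle(self):
        fit = models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial"))
        llf, va, vb, ve = crossed_lmm_ml_oracle(
            CROSSED_FIXTURE["body_mass"], CROSSED_FIXTURE["ecoregion"],
            CROSSED_FIXTURE["source"])
        assert fit.llf == pytest.approx(llf, abs=1e-3)
        assert fit.vcomp["ecoregion"] == pytest.approx(va, abs=1e-3)
        assert fit.vcomp["source"] == pytest.approx(vb, abs=1e-3)
        assert fit.sigma2_resid == pytest.approx(ve, abs=1e-3)

    def test_no_group_structure_collapses_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame({
            "body_mass": rng.normal(20, 2, n),
            "MAT_std": rng.normal(size=n),
            "ecoregion": rng.choice(list("ABCD"), n),
            "source": rng.choice(["VertNet", "NACSM", "NEON"], n),
        })
        fit = models.fit_lmm(df, ModelSpec("body_mass", ("MAT",), "spatial"))
        ols = sm.OLS(df["body_mass"], sm.add_constant(df["MAT_std"])).fit()
        assert fit.params["Intercept"] == pytest.approx(ols.params.iloc[0],
                                                        abs=1e-6)
        assert fit.params["MAT_std"] == pytest.approx(ols.params.iloc[1],
                                                      abs=1e-6)

    def test_single_level_grouping_rejected(self):
        df = CROSSED_FIXTURE.assign(source="S")
        with pytest.raises(ValueError, match="levels"):
            models.fit_lmm(df, ModelSpec("body_mass", (), "spatial"))

    def test_k_counts_all_parameters(self, bundle):
        prep = workflow.prepare_dataset(bundle, "body_mass", "spatial")
        fit = models.fit_lmm(prep.data, ModelSpec("body_mass", ("MAT", "sex"),
                                                  "spatial"))
        # 3 fixed + 2 variance components + residual
        assert fit.k == fit.n_fixed + 3
        assert fit.aicc >= fit.aic


class TestRanking:
    def test_weights_closed_form(self):
        base = models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial"))
        import copy

        f1, f2 = copy.deepcopy(base), copy.deepcopy(base)
        f1.aicc, f2.aicc = 100.0, 102.0
        sel = models.rank_models([f2, f1])
        w = np.exp(-np.array([0.0, 2.0]) / 2)
        w /= w.sum()
        np.testing.assert_allclose(sel.table["weight"], w, atol=1e-12)
        assert sel.table["weight"].iloc[0] == pytest.approx(0.7311, abs=1e-4)
        assert sel.table["delta_aicc"].iloc[0] == 0.0

    def test_weights_sum_to_one(self, bundle):
        prep = workflow.prepare_dataset(bundle, "body_mass", "spatial")
        fits = [models.fit_lmm(prep.data, s) for s in
                models.enumerate_candidates("body_mass", "spatial",
                                            explicit=[(), ("MAT",),
                                                      ("MAT", "MAP"),
                                                      ("sex",)])]
        sel = models.rank_models(fits)
        assert sel.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_model_weight_one(self):
        fit = models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial"))
        sel = models.rank_models([fit])
        assert sel.table["weight"].iloc[0] == 1.0

    def test_identical_aicc_equal_weights_stable_order(self):
        import copy

        base = models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial"))
        f1, f2 = copy.deepcopy(base), copy.deepcopy(base)
        f1.spec = ModelSpec("body_mass", ("MAT",), "spatial")
        f1.aicc = f2.aicc
        sel = models.rank_models([f1, f2])
        np.testing.assert_allclose(sel.table["weight"], [0.5, 0.5])
        assert list(sel.table["name"]) == sorted(sel.table["name"])

    def test_all_failed_rejected(self):
        import copy

        fit = copy.deepcopy(
            models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial")))
        fit.converged = False
        with pytest.raises(ValueError):
            models.rank_models([fit])


class TestNakagawaR2:
    def test_plug_in_values(self):
        import copy

        fit = copy.deepcopy(
            models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial")))
        fit.fixed_predictor_var = 2.0
        fit.vcomp = {"ecoregion": 0.6, "source": 0.4}
        fit.sigma2_resid = 1.0
        marginal, conditional = models.nakagawa_r2(fit)
        assert marginal == pytest.approx(0.5)
        assert conditional == pytest.approx(0.75)

    def test_intercept_only_marginal_zero(self):
        fit = models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial"))
        marginal, conditional = models.nakagawa_r2(fit)
        assert marginal == pytest.approx(0.0, abs=1e-12)
        assert conditional >= marginal

    def test_ordering_and_bounds_on_real_fit(self, bundle):
        prep = workflow.prepare_dataset(bundle, "body_mass", "spatial")
        fit = models.fit_lmm(prep.data,
                             ModelSpec("body_mass", models.SPATIAL_GLOBAL,
                                       "spatial"))
        marginal, conditional = models.nakagawa_r2(fit, prep.data)
        assert 0.0 <= marginal <= conditional <= 1.0


class TestDiagnostics:
    def test_requires_random_slope(self):
        fit = models.fit_lmm(CROSSED_FIXTURE, ModelSpec("body_mass", (), "spatial"))
        with pytest.raises(ValueError, match="slope"):
            models.random_effect_diagnostics(fit)

    def test_two_zone_degenerate_flagged(self):
        rng = np.random.default_rng(8)
        n = 120
        df = pd.DataFrame({
            "body_mass": rng.normal(20, 1, n),
            "decade_std": rng.normal(size=n),
            "zone": np.repeat(["a", "b"], n // 2),
        })
        fit = models.fit_lmm(df, ModelSpec("body_mass", ("decade",), "temporal"))
        diag = models.random_effect_diagnostics(fit)
        assert not diag["reliable"]

    def test_recovers_negative_coupling(self, bundle):
        prep = workflow.prepare_dataset(bundle, "body_mass", "temporal",
                                        zone_source="lattice")
        fit = models.fit_lmm(prep.data,
                             ModelSpec("body_mass", models.TEMPORAL_GLOBAL,
                                       "temporal"))
        diag = models.random_effect_diagnostics(fit)
        assert diag["model_corr"] < 0
        assert diag["empirical_corr"] < 0
        assert len(diag["table"]) == prep.data["zone"].nunique()


class TestPerZoneTrends:
    def test_exact_linear_decline(self):
        decades = np.tile(np.arange(6, 14), 3)
        df = pd.DataFrame({
            "zone": np.repeat(["a", "b", "c"], 8),
            "decade_index": decades,
            "body_mass": 20.0 - 0.1 * decades,
        })
        out = models.fit_per_zone_trends(df, "body_mass")
        np.testing.assert_allclose(out["slope"], -0.1, atol=1e-12)

    def test_constant_size_zero_slope(self):
        df = pd.DataFrame({"zone": ["a"] * 6,
                           "decade_index": [6, 7, 8, 9, 10, 11],
                           "body_mass": [20.0] * 6})
        out = models.fit_per_zone_trends(df, "body_mass")
        assert out["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_decade_zone_skipped(self):
        df = pd.DataFrame({"zone": ["a"] * 5 + ["b"] * 5,
                           "decade_index": [6] * 5 + [6, 7, 8, 9, 10],
                           "body_mass": np.arange(10.0)})
        out = models.fit_per_zone_trends(df, "body_mass")
        assert list(out["zone"]) == ["b"]
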