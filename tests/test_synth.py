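"""Generator contracts: determinism, construction guarantees, and
self-consistency of the drawn effects with the declared truth."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from sizeclines import synth
from sizeclines.synth import GenerativeTruth

BOUNDS = (-110.0, 32.0, -90.0, 46.0)


@pytest.fixture(scope="module")
def layers():
    mat, mp = synth.make_climate_surfaces(BOUNDS, range(1895, 2020), seed=5)
    dens = synth.make_density_stack(BOUNDS, list(range(1890, 2011, 10)),
                                    n_cities=10, seed=6)
    eco = synth.make_ecoregions(BOUNDS)
    return mat, mp, dens, eco


class TestClimateSurfaces:
    def test_no_trend_layers_identical(self):
        mat, _ = synth.make_climate_surfaces(BOUNDS, [1950, 2010], seed=1,
                                             warming_trend=0.0)
        np.testing.assert_array_equal(mat.layer(1950), mat.layer(2010))

    def test_trend_shifts_domain_mean(self):
        mat, _ = synth.make_climate_surfaces(BOUNDS, [1950, 2000], seed=1,
                                             warming_trend=0.02)
        diff = mat.layer(2000).mean() - mat.layer(1950).mean()
        assert diff == pytest.approx(1.0)

    def test_seed_determinism(self):
        a, _ = synth.make_climate_surfaces(BOUNDS, [1950], seed=9)
        b, _ = synth.make_climate_surfaces(BOUNDS, [1950], seed=9)
        np.testing.assert_array_equal(a.layer(1950), b.layer(1950))

    def test_mat_declines_with_latitude(self):
        mat, _ = synth.make_climate_surfaces(BOUNDS, [1950], seed=2)
        rowmeans = mat.layer(1950).mean(axis=1)  # row 0 = south
        assert rowmeans[0] > rowmeans[-1]

    @pytest.mark.parametrize("bad", [[], None])
    def test_empty_years_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            synth.make_climate_surfaces(BOUNDS, bad or [], seed=0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            synth.make_climate_surfaces((-90, 40, -100, 45), [1950], seed=0)


class TestDensityStack:
    def test_zero_cities_is_uniform_floor(self):
        d = synth.make_density_stack(BOUNDS, [1950, 1960], n_cities=0, seed=3)
        assert (d.layer(1950) == synth.DENSITY_FLOOR).all()

    def test_density_nondecreasing_over_decades(self):
        d = synth.make_density_stack(BOUNDS, list(range(1890, 2011, 10)),
                                     n_cities=8, seed=4)
        for a, b in zip(d.times, d.times[1:]):
            assert (d.layer(b) >= d.layer(a)).all()

    def test_seed_reproducibility(self):
        a = synth.make_density_stack(BOUNDS, [1950], n_cities=5, seed=8)
        b = synth.make_density_stack(BOUNDS, [1950], n_cities=5, seed=8)
        np.testing.assert_array_equal(a.layer(1950), b.layer(1950))

    def test_negative_cities_rejected(self):
        with pytest.raises(ValueError):
            synth.make_density_stack(BOUNDS, [1950], n_cities=-1, seed=0)

    def test_unsorted_decades_rejected(self):
        with pytest.raises(ValueError):
            synth.make_density_stack(BOUNDS, [1960, 1950], n_cities=2, seed=0)


class TestSimulateRecords:
    def test_determinism(self, layers):
        mat, mp, dens, eco = layers
        kw = dict(n=500, year_range=(1945, 2019), seed=21, n_zones=8,
                  bounds=BOUNDS)
        a = synth.simulate_records(GenerativeTruth(), (mat, mp), dens, eco, **kw)
        b = synth.simulate_records(GenerativeTruth(), (mat, mp), dens, eco, **kw)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_degenerate_truth_mass_is_offsets_plus_noise(self, layers):
        mat, mp, dens, eco = layers
        truth = GenerativeTruth.null()
        truth.sex_offset = 1.0
        truth.season_offsets = {"Fall": 0.0, "Spring": 2.0, "Summer": 1.0,
                                "Winter": 0.5}
        sim = synth.simulate_records(truth, (mat, mp), dens, eco, n=6000,
                                     year_range=(1945, 2019), seed=22,
                                     n_zones=8, bounds=BOUNDS)
        df = sim.records.copy()
        df["mass"] = pd.to_numeric(df["body_mass"], errors="coerce")
        df = df[df["mass"].notna()]
        from sizeclines.harmonize import assign_season

        df["season"] = [assign_season(m, d) for m, d in zip(df["month"], df["day"])]
        for (sex, season), grp in df.groupby(["sex", "season"]):
            expected = (truth.intercept + truth.season_offsets[season]
                        + (truth.sex_offset if sex == "female" else 0.0))
            tol = 3 * truth.sigma_resid / np.sqrt(len(grp))
            assert abs(grp["mass"].mean() - expected) < tol, (sex, season)

    def test_zone_effect_correlation_matches_rho(self, layers):
        mat, mp, dens, eco = layers
        truth = GenerativeTruth(rho_slope_intercept=-0.9)
        sim = synth.simulate_records(truth, (mat, mp), dens, eco, n=4000,
                                     year_range=(1945, 2019), seed=23,
                                     n_zones=40, bounds=BOUNDS)
        ze = sim.zone_effects
        # restrict to the generator's 40 sampled zones (scatter creates
        # extra sparse lattice cells)
        counts = sim.truth_records["true_zone"].value_counts()
        main = counts[counts > 20].index
        ze = ze[ze["zone"].isin(main)]
        r = np.corrcoef(ze["intercept_effect"], ze["slope_effect"])[0, 1]
        assert abs(r - (-0.9)) < 0.15

    def test_juvenile_injection_rate(self, layers):
        mat, mp, dens, eco = layers
        truth = GenerativeTruth(juvenile_frac=0.1)
        sim = synth.simulate_records(truth, (mat, mp), dens, eco, n=10_000,
                                     year_range=(1945, 2019), seed=24,
                                     n_zones=10, bounds=BOUNDS)
        n_juv = (sim.truth_records["truth_class"] == "juvenile").sum()
        assert 900 <= n_juv <= 1100
        labelled = (sim.records["life_stage"] == "juvenile").sum()
        assert labelled == n_juv  # bookkeeping is exact

    def test_contamination_classes_modify_records(self, layers):
        mat, mp, dens, eco = layers
        sim = synth.simulate_records(GenerativeTruth(), (mat, mp), dens, eco,
                                     n=8000, year_range=(1945, 2019), seed=25,
                                     n_zones=10, bounds=BOUNDS)
        rec = sim.records
        cls = sim.truth_records["truth_class"]
        amb = rec.loc[cls == "ambig_sex", "sex"]
        assert (~amb.isin(["female", "male"])).all()
        sub = pd.to_numeric(rec.loc[cls == "sub9g", "body_mass"])
        assert (sub < 9).all()
        for i in rec.index[cls == "bad_date"]:
            y, m, d = rec.loc[i, ["year", "month", "day"]]
            assert y < 1895 or pd.isna(m) or (m == 1 and d == 1)

    def test_neon_hb_bias_is_negative_and_detectable(self, layers):
        mat, mp, dens, eco = layers
        sim = synth.simulate_records(GenerativeTruth(), (mat, mp), dens, eco,
                                     n=12_000, year_range=(1990, 2019), seed=26,
                                     n_zones=10, bounds=BOUNDS)
        rec = sim.records[sim.truth_records["truth_class"].to_numpy() == "clean"]
        hb = (pd.to_numeric(rec["total_length"], errors="coerce")
              - pd.to_numeric(rec["tail_length"], errors="coerce"))
        ok = hb.notna()
        neon = rec["source"] == "NEON"
        gap = hb[ok & neon].mean() - hb[ok & ~neon].mean()
        assert gap < -2.0  # live-capture lengths read short

    def test_year_coverage_enforced(self, layers):
        mat, mp, dens, eco = layers
        with pytest.raises(ValueError, match="cover"):
            synth.simulate_records(GenerativeTruth(), (mat, mp), dens, eco,
                                   n=10, year_range=(1850, 2019), seed=0,
                                   bounds=BOUNDS)

    def test_ols_self_consistency(self, layers):
        """With the random-effect SDs at zero, OLS on the true
        standardized covariates recovers every beta within 3 SE."""
        mat, mp, dens, eco = layers
        truth = GenerativeTruth(sigma_ecoregion=0, sigma_source=0,
                                sigma_zone_intercept=0, sigma_zone_slope=0,
                                juvenile_frac=0, sub9g_frac=0, bad_date_frac=0,
                                ambig_sex_frac=0, outlier_frac=0)
        sim = synth.simulate_records(truth, (mat, mp), dens, eco, n=20_000,
                                     year_range=(1945, 2019), seed=27,
                                     n_zones=20, bounds=BOUNDS)
        df = sim.records.merge(sim.truth_records, on="record_id")
        df["mass"] = pd.to_numeric(df["body_mass"], errors="coerce")
        df = df[df["mass"].notna()]
        from sizeclines.harmonize import assign_season

        df["season"] = [assign_season(m, d) for m, d in zip(df["month"], df["day"])]
        res = smf.ols("mass ~ z_mat + z_map + z_density + z_decade"
                      " + C(sex) + C(season)", df).fit()
        for term, true_val in [("z_mat", truth.beta_mat),
                               ("z_map", truth.beta_map),
                               ("z_density", truth.beta_density),
                               ("z_decade", truth.beta_decade)]:
            assert abs(res.params[term] - true_val) <= 3 * res.bse[term], term
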