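"""Attributable fractions, burden accounting, apportionment, curve statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coalburden.burden import (attributable_fraction, burden_share,
                               compare_rrs, compute_burden,
                               concentration_curve, apportion_to_egus,
                               project_deaths)
from coalburden.crf import CRFEstimate


def crf(beta, se=0.0):
    return CRFEstimate(beta=beta, se_beta=se, converged=True, n_obs=0,
                       loglike=float("nan"), descriptor={})


class TestAttributableFraction:
    def test_values(self):
        assert attributable_fraction(0.5, 0.0) == 0.0
        beta = np.log(1.0125)
        assert attributable_fraction(beta, 1.0) == pytest.approx(
            1 - 1 / 1.0125, rel=1e-10)  # ~0.0123457
        assert attributable_fraction(10.0, 1e6) == pytest.approx(1.0)

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(0.1, -1.0)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(beta=st.floats(0, 5), x=st.floats(0, 5))
    def test_fraction_bounded_and_monotone_in_beta(self, beta, x):
        af = attributable_fraction(beta, x)
        assert 0.0 <= af < 1.0
        assert attributable_fraction(beta + 0.1, x) >= af


class TestComputeBurden:
    def test_excess_is_deaths_times_af(self):
        deaths = pd.DataFrame({"zip_id": [0], "year": [2000], "deaths": [1000]})
        exp = pd.DataFrame({"zip_id": [0], "year": [2000], "coal_pm25": [1.0]})
        tbl = compute_burden(deaths, exp, crf(np.log(1.0125)))
        assert tbl.total() == pytest.approx(1000 * (1 - 1 / 1.0125))  # 12.35

    def test_zero_exposure_zero_burden(self):
        deaths = pd.DataFrame({"zip_id": [0, 1], "year": 2000,
                               "deaths": [100, 200]})
        exp = pd.DataFrame({"zip_id": [0, 1], "year": 2000, "coal_pm25": 0.0})
        tbl = compute_burden(deaths, exp, crf(0.05, 0.01))
        assert tbl.total() == 0.0
        lo, hi = tbl.total_ci()
        assert lo == hi == 0.0

    def test_ci_brackets_point(self):
        deaths = pd.DataFrame({"zip_id": [0], "year": [2000], "deaths": [500]})
        exp = pd.DataFrame({"zip_id": [0], "year": [2000], "coal_pm25": [2.0]})
        tbl = compute_burden(deaths, exp, crf(0.01, 0.002))
        row = tbl.zip_year.iloc[0]
        assert row["ci_low"] <= row["excess_deaths"] <= row["ci_high"]

    def test_projection_is_trailing_three_year_mean(self):
        deaths = pd.DataFrame({
            "zip_id": [0] * 5, "year": [2000, 2001, 2002, 2003, 2004],
            "deaths": [10, 20, 30, 40, 50]})
        out = project_deaths(deaths, [2005, 2006], trailing=3)
        proj = out[out["year"].isin([2005, 2006])]
        np.testing.assert_allclose(proj["deaths"], (30 + 40 + 50) / 3)

    def test_projection_requires_three_trailing_years(self):
        deaths = pd.DataFrame({"zip_id": [0, 0], "year": [2000, 2001],
                               "deaths": [10, 20]})
        with pytest.raises(ValueError, match=">= 3 observed years"):
            project_deaths(deaths, [2002], trailing=3)


class TestApportionment:
    def test_proportional_split(self):
        deaths = pd.DataFrame({"zip_id": [0], "year": [2000], "deaths": [973]})
        field = pd.DataFrame({"zip_id": [0, 0], "year": 2000,
                              "egu_id": [0, 1], "coal_pm25": [3.0, 1.0],
                              "metric_tag": "scaled"})
        exp = pd.DataFrame({"zip_id": [0], "year": [2000], "coal_pm25": [4.0]})
        est = crf(0.003171)
        tbl = compute_burden(deaths, exp, est)
        per = apportion_to_egus(tbl, field)
        total = tbl.total()
        assert per.loc[per["egu_id"] == 0, "excess_deaths"].iloc[0] == \
            pytest.approx(0.75 * total)
        assert per.loc[per["egu_id"] == 1, "excess_deaths"].iloc[0] == \
            pytest.approx(0.25 * total)

    def test_conservation_on_synthetic_world(self, small_world, small_config,
                                             small_raw):
        from coalburden.calibration import (apply_scaling, field_totals,
                                            fit_scaling)
        from coalburden.dispersion import exposure_totals

        tot = exposure_totals(small_raw, small_config)
        model = fit_scaling(tot, small_world["concentrations"],
                            small_config.start_year)
        scaled = apply_scaling(small_raw, model)
        stot = field_totals(scaled, small_config)
        deaths = (small_world["panel"].groupby(["zip_id", "year"])["deaths"]
                  .sum().reset_index())
        tbl = compute_burden(deaths, stot, crf(0.0123, 0.001))
        per = apportion_to_egus(tbl, scaled)
        assert per["excess_deaths"].sum() == pytest.approx(
            tbl.total(), rel=1e-9)

    def test_rank_matches_brute_force_oracle(self):
        """3-EGU toy world: apportioned-death rank equals the rank of the
        death-weighted emissions x transport-kernel functional."""
        from coalburden.config import WorldConfig
        from coalburden.dispersion import analytic_kernel
        from coalburden.synthetic_world import true_coal_field

        cfg = WorldConfig(n_egus=3, n_years=1, grid_size=7,
                          wind_mean=(0.3, 0.0), diffusion_sd=0.5, seed=2)
        inv = pd.DataFrame({
            "egu_id": [0, 1, 2], "x": [1, 3, 5], "y": [3, 1, 5],
            "year": cfg.start_year, "so2_emissions": [90.0, 30.0, 10.0],
            "scrubber_year": pd.array([None] * 3, dtype="Int64"),
            "retire_year": pd.array([None] * 3, dtype="Int64")})
        field = true_coal_field(inv, cfg)  # exact per-EGU-linear exposure
        per_egu_field = []
        rng = np.random.default_rng(4)
        deaths_by_zip = rng.integers(50, 200, size=cfg.n_zips).astype(float)
        oracle_score = {}
        for _, r in inv.iterrows():
            kern = analytic_kernel((r["x"] + 0.5, r["y"] + 0.5), cfg)
            vals = cfg.truth_scale * r["so2_emissions"] * kern
            per_egu_field.append(pd.DataFrame({
                "zip_id": np.arange(cfg.n_zips), "year": cfg.start_year,
                "egu_id": r["egu_id"], "coal_pm25": vals,
                "metric_tag": "scaled"}))
            oracle_score[r["egu_id"]] = float((deaths_by_zip * vals).sum())
        per_field = pd.concat(per_egu_field, ignore_index=True)
        deaths = pd.DataFrame({"zip_id": np.arange(cfg.n_zips),
                               "year": cfg.start_year,
                               "deaths": deaths_by_zip})
        tbl = compute_burden(deaths, field.rename(
            columns={"true_coal_pm25": "coal_pm25"}), crf(0.01))
        per = apportion_to_egus(tbl, per_field)
        got_rank = (per.groupby("egu_id")["excess_deaths"].sum()
                    .sort_values(ascending=False).index.tolist())
        want_rank = sorted(oracle_score, key=oracle_score.get, reverse=True)
        assert got_rank == want_rank


class TestCompareRRs:
    def test_per_10ug_unit_conversion(self):
        deaths = pd.DataFrame({"zip_id": [0], "year": [2000], "deaths": [100]})
        exp = pd.DataFrame({"zip_id": [0], "year": [2000], "coal_pm25": [1.0]})
        out = compare_rrs(deaths, exp,
                          [{"label": "general", "rr": 1.016, "per_ug": 10.0}])
        assert out["rr_per_unit"].iloc[0] == pytest.approx(
            np.exp(np.log(1.016) / 10), rel=1e-12)  # ~1.001588

    def test_identical_specs_identical_burden(self, small_world):
        deaths = (small_world["panel"].groupby(["zip_id", "year"])["deaths"]
                  .sum().reset_index())
        exp = small_world["concentrations"].rename(
            columns={"true_coal_pm25": "coal_pm25"})
        specs = [{"label": "a", "rr": 1.01, "per_ug": 1.0},
                 {"label": "b", "rr": 1.01, "per_ug": 1.0}]
        out = compare_rrs(deaths, exp[["zip_id", "year", "coal_pm25"]], specs)
        assert out["total_excess_deaths"].iloc[0] == \
            out["total_excess_deaths"].iloc[1]

    def test_larger_rr_strictly_larger_burden(self, small_world):
        deaths = (small_world["panel"].groupby(["zip_id", "year"])["deaths"]
                  .sum().reset_index())
        exp = small_world["concentrations"].rename(
            columns={"true_coal_pm25": "coal_pm25"})
        specs = [{"label": "lo", "rr": 1.005}, {"label": "hi", "rr": 1.02}]
        out = compare_rrs(deaths, exp[["zip_id", "year", "coal_pm25"]], specs)
        assert out.loc[1, "total_excess_deaths"] > out.loc[0, "total_excess_deaths"]

    def test_rejects_null_rr(self):
        deaths = pd.DataFrame({"zip_id": [0], "year": [2000], "deaths": [1]})
        exp = pd.DataFrame({"zip_id": [0], "year": [2000], "coal_pm25": [1.0]})
        with pytest.raises(ValueError, match="must be > 1"):
            compare_rrs(deaths, exp, [{"label": "x", "rr": 1.0}])


class TestHeadlineStatistics:
    def test_burden_share_values(self):
        assert burden_share(460_000, 38.6e6) == 1.2
        assert burden_share(0.0, 100.0) == 0.0
        assert burden_share(100.0, 100.0) == 100.0

    def test_burden_share_zero_denominator(self):
        with pytest.raises(ValueError):
            burden_share(1.0, 0.0)

    def test_concentration_curve_prefix(self):
        e = pd.Series([60.0, 40.0])
        d = pd.Series([90.0, 10.0])
        assert concentration_curve(d, e, 0.5) == pytest.approx(0.90)
        assert concentration_curve(d, e, 1.0) == 1.0

    def test_concentration_curve_uniform_case(self):
        n = 20
        e = pd.Series(np.ones(n))
        d = pd.Series(np.ones(n))
        share = concentration_curve(d, e, 0.5)
        assert abs(share - 0.5) <= 1.0 / n

    def test_concentration_curve_bad_quantile(self):
        with pytest.raises(ValueError):
            concentration_curve(pd.Series([1.0]), pd.Series([1.0]), 0.0)
        with pytest.raises(ValueError):
            concentration_curve(pd.Series([1.0]), pd.Series([1.0]), 1.5)
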