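"""Transforms, OLS fits, RMSE back-transform, classification, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aopipe import aor_models
from aopipe.aor_models import (
    UnfittableGroupError, classify_strength, fit_relationship, rmse_bt,
    run_all_scales, summarize_fits, transform_xy,
)


class TestTransform:
    def test_logit_values(self):
        x, _, _ = transform_xy([0.5, 0.62, 0.3], [1, 1, 1], [100, 100, 100])
        assert x[0] == pytest.approx(0.0)
        assert x[1] == pytest.approx(math.log(0.62 / 0.38), abs=1e-4)

    def test_zero_response_uniform_shift(self):
        _, y, spec = transform_xy([0.2, 0.4, 0.6], [0.0, 5.0, 10.0],
                                  [10, 10, 10])
        assert spec.response_adjust == 5.0
        assert np.allclose(y, np.log10([5.0, 10.0, 15.0]))

    def test_no_adjustment_without_zeros(self):
        _, y, spec = transform_xy([0.2, 0.4, 0.6], [1.0, 5.0, 10.0],
                                  [10, 10, 10])
        assert spec.response_adjust == 0.0
        assert spec.occupancy_adjust == 0.0
        assert np.allclose(y, np.log10([1.0, 5.0, 10.0]))

    def test_occupancy_zero_and_one_adjusted(self):
        x, _, spec = transform_xy([0.0, 0.5, 1.0], [1, 2, 3], [100, 100, 50])
        lo = 0.5 / 100
        hi = 1 - 0.5 / 50
        assert x[0] == pytest.approx(math.log(lo / (1 - lo)))
        assert x[2] == pytest.approx(math.log(hi / (1 - hi)))
        assert spec.n_adjusted_occupancies == 2
        assert spec.occupancy_adjust == pytest.approx(0.5 / 50)

    def test_degenerate_sets_rejected(self):
        with pytest.raises(UnfittableGroupError, match="all responses zero"):
            transform_xy([0.1, 0.2, 0.3], [0, 0, 0], [10, 10, 10])
        with pytest.raises(UnfittableGroupError, match="constant occupancy"):
            transform_xy([0.4, 0.4, 0.4], [1, 2, 3], [10, 10, 10])
        with pytest.raises(UnfittableGroupError, match="units"):
            transform_xy([0.1, 0.2], [1, 2], [10, 10])


class TestFitRelationship:
    def test_exact_line(self):
        x = np.arange(8, dtype=float)
        fit = fit_relationship(x, 2 + 0.5 * x)
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.rmse_bt == pytest.approx(0.0, abs=1e-9)
        assert fit.significant

    def test_negative_slope_representable(self):
        x = np.arange(8, dtype=float)
        fit = fit_relationship(x, 2 - 0.5 * x)
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(3, 11)
            x = rng.standard_normal(n)
            if np.ptp(x) == 0:
                continue
            y = rng.standard_normal(n)
            fit = fit_relationship(x, y)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)
            resid = y - X @ beta
            sst = np.sum((y - y.mean()) ** 2)
            assert fit.r_squared == pytest.approx(
                1 - resid @ resid / sst, abs=1e-10)
            assert fit.rmse == pytest.approx(
                math.sqrt(resid @ resid / n), abs=1e-10)

    def test_rmse_denominator_option(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal(8), rng.standard_normal(8)
        f_n = fit_relationship(x, y, rmse_denominator="n")
        f_n2 = fit_relationship(x, y, rmse_denominator="n-2")
        assert f_n2.rmse == pytest.approx(f_n.rmse * math.sqrt(8 / 6))

    def test_degenerate_inputs(self):
        with pytest.raises(UnfittableGroupError):
            fit_relationship([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(UnfittableGroupError):
            fit_relationship([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_r2_invariant_under_affine_y_rescale(self, a, b):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(10)
        y = 1.0 + 0.5 * x + 0.3 * rng.standard_normal(10)
        f1 = fit_relationship(x, y)
        f2 = fit_relationship(x, a * y + b)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-9)
        assert f2.slope == pytest.approx(a * f1.slope, abs=1e-9)


class TestRmseBt:
    def test_anchor_values(self):
        assert rmse_bt(0.0) == 0.0
        assert rmse_bt(math.log10(2)) == pytest.approx(100.0)
        assert rmse_bt(math.log10(1.5)) == pytest.approx(50.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rmse_bt(-0.1)

    @given(st.floats(0.0, 2.0), st.floats(0.001, 1.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_and_convex(self, r, dr):
        # increasing, and the secant slope grows with r (convexity)
        lo, hi = rmse_bt(r), rmse_bt(r + dr)
        assert hi > lo
        assert rmse_bt(r + 2 * dr) - hi > hi - lo


class TestClassification:
    @pytest.mark.parametrize("r2,bt,expected", [
        (0.83, 15.0, "strong"),
        (0.46, 90.0, "weak"),
        (0.53, 49.0, "strong"),   # strict boundary comparisons
        (0.50, 50.0, "weak"),
        (0.53, 142.0, "mixed"),   # large R2 but large error
        (0.08, 45.0, "mixed"),    # small error but small R2
    ])
    def test_rules(self, r2, bt, expected):
        assert classify_strength(r2, bt) == expected

    def test_proportion_domain(self):
        with pytest.raises(ValueError):
            classify_strength(53.0, 15.0)  # percent passed by mistake


class TestSummaries:
    def test_single_fit_degenerate_summary(self):
        fits = pd.DataFrame([{
            "species": "s", "scale": "regional_temporal",
            "response": "abundance", "status": "ok", "intercept": 2.0,
            "slope": 0.5, "r_squared": 0.9, "rmse_bt": 12.0}])
        out = summarize_fits(fits).iloc[0]
        assert out.slope_median == 0.5 and out.slope_iqr == 0.0
        assert out.rmse_bt_median == 12.0

    def test_median_and_iqr_convention(self):
        fits = pd.DataFrame([
            {"species": "s", "scale": "local_temporal",
             "response": "abundance", "status": "ok", "intercept": 0.0,
             "slope": sl, "r_squared": 0.5, "rmse_bt": 10.0}
            for sl in (0.1, 0.2, 0.4)])
        out = summarize_fits(fits).iloc[0]
        assert out.slope_median == pytest.approx(0.2)
        # independent quantile computation, linear interpolation:
        # q25 = 0.15, q75 = 0.30
        assert out.slope_iqr == pytest.approx(0.30 - 0.15)


def _toy_summaries(n_species=2, n_years=8, n_basins=3, seed=0):
    """Stacked regional + basin-year summaries with plausible structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_species):
        for year in range(2008, 2008 + n_years):
            units = [("regional_temporal", pd.NA, 300)] + [
                ("local_temporal", f"B{b}", 100) for b in range(n_basins)]
            for scale, basin, n in units:
                occ = float(np.clip(rng.uniform(0.05, 0.9), 0, 1))
                npres = int(round(occ * n))
                rows.append({
                    "species": f"sp{s}", "scale": scale, "basin_id": basin,
                    "year": year, "n_stations": n, "n_present": npres,
                    "occupancy": npres / n,
                    "local_mean_abundance": rng.uniform(10, 500)
                    if npres else np.nan,
                    "local_mean_biomass": rng.uniform(0.1, 5)
                    if npres else np.nan})
    return pd.DataFrame(rows)


class TestRunAllScales:
    def test_regional_bookkeeping(self):
        summ = _toy_summaries(n_species=2)
        fits, _ = run_all_scales(summ, scales=("regional_temporal",))
        ok = fits[fits.status == "ok"]
        assert len(ok) <= 2 * 2  # species x responses
        assert (ok.n_points == 8).all()
        assert (ok.scale == "regional_temporal").all()

    def test_local_respects_inclusion_filter(self):
        summ = _toy_summaries()
        # species sp0 never present in basin B0
        m = (summ.species == "sp0") & (summ.basin_id == "B0")
        summ.loc[m, ["n_present", "occupancy"]] = 0
        summ.loc[m, ["local_mean_abundance", "local_mean_biomass"]] = np.nan
        fits, _ = run_all_scales(summ, scales=("local_temporal",))
        assert not ((fits.species == "sp0") & (fits.group == "B0")).any()

    def test_unfittable_groups_reported_not_dropped(self):
        summ = _toy_summaries(n_species=1)
        m = summ.scale == "regional_temporal"
        summ.loc[m, ["n_present"]] = 0
        summ.loc[m, "occupancy"] = 0.0
        summ.loc[m, ["local_mean_abundance", "local_mean_biomass"]] = np.nan
        fits, _ = run_all_scales(summ, scales=("regional_temporal",))
        assert len(fits) == 2
        assert fits.status.str.startswith("skipped").all()
        assert fits.status.str.contains("all responses zero").all()

    def test_spatial_groups_by_year(self):
        summ = _toy_summaries()
        fits, _ = run_all_scales(summ, scales=("spatial",))
        ok = fits[fits.status == "ok"]
        assert set(ok.group.astype(int)) <= set(range(2008, 2016))
        assert (ok.n_points == 3).all()  # three basins per year

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="unknown scales"):
            run_all_scales(_toy_summaries(), scales=("global",))
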