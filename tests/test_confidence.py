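"""F-test confidence surfaces and the multi-start minima census."""

import numpy as np
import pytest
from scipy import stats

import ivimfit as iv
from ivimfit.confidence import (
    DegenerateSurfaceError,
    EmptyCensusError,
    confidence_grid,
    default_start_grid,
    ftest_probability,
    minima_census,
)
from ivimfit.fitting import MethodSpec


def noisy_curve(params, snr, seed, n=1):
    cfg = iv.SimulationConfig(
        model_params=params, snr_levels=(float(snr),), n_iterations=n, seed=seed
    )
    records = iv.generate_ensemble(cfg)
    return [r.curve for r in records] if n > 1 else records[0].curve


class TestFTestFormula:
    def test_null_point_has_zero_probability(self):
        assert ftest_probability(1.0, 1.0, 11, 1, 2) == 0.0
        # numerical cost decreases clip to zero rather than going negative
        assert ftest_probability(0.999, 1.0, 11, 1, 2) == 0.0

    def test_degenerate_and_invalid(self):
        with pytest.raises(DegenerateSurfaceError):
            ftest_probability(1.0, 0.0, 11, 1, 2)
        with pytest.raises(iv.ValidationError):
            ftest_probability(2.0, 1.0, 3, 3, 1)

    def test_straight_line_profile_matches_t_interval(self):
        # 1D analogue with a closed-form answer: for a straight line fit by
        # OLS, the F(1, n-2) fixed-slope test is exactly the squared-t test,
        # so the 0.95 crossing of the profile must reproduce the textbook
        # slope confidence interval within grid resolution
        rng = np.random.default_rng(42)
        x = np.arange(12.0)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.5, size=x.size)
        n = x.size
        xb, yb = x.mean(), y.mean()
        sxx = ((x - xb) ** 2).sum()
        slope = ((x - xb) * (y - yb)).sum() / sxx
        intercept = yb - slope * xb
        chi2_best = ((y - intercept - slope * x) ** 2).sum()
        se_slope = np.sqrt(chi2_best / (n - 2) / sxx)
        t975 = stats.t.ppf(0.975, n - 2)
        ci = (slope - t975 * se_slope, slope + t975 * se_slope)

        grid = np.linspace(slope - 6 * se_slope, slope + 6 * se_slope, 801)
        prob = []
        for s_fix in grid:
            a_fix = yb - s_fix * xb  # closed-form intercept re-fit
            chi2 = ((y - a_fix - s_fix * x) ** 2).sum()
            prob.append(ftest_probability(chi2, chi2_best, n, 2, 1))
        prob = np.asarray(prob)
        inside = grid[prob <= 0.95]
        cell = grid[1] - grid[0]
        assert inside.min() == pytest.approx(ci[0], abs=cell)
        assert inside.max() == pytest.approx(ci[1], abs=cell)


@pytest.fixture(scope="module")
def gm20_fit():
    curve = noisy_curve(iv.GM_PARAMS, 20, seed=15)
    best = iv.fit_one_parameter(curve)
    assert not best.outlier
    return curve, best


class TestConfidenceGrid:
    def test_surface_bounds_and_minimum_at_best_fit(self, gm20_fit):
        curve, best = gm20_fit
        grid = confidence_grid(
            curve, best, ("f", "D_star"), MethodSpec("one_parameter"), n_points=21
        )
        assert grid.probability.min() >= 0.0
        assert grid.probability.max() <= 1.0
        # the surface minimum sits at (or adjacent to) the best-fit node
        i, j = np.unravel_index(grid.probability.argmin(), grid.probability.shape)
        bi = np.abs(grid.axes[0] - best.estimate.f).argmin()
        bj = np.abs(grid.axes[1] - best.estimate.D_star).argmin()
        assert abs(int(i) - int(bi)) <= 1 and abs(int(j) - int(bj)) <= 1

    def test_transposing_pair_transposes_surface(self, gm20_fit):
        curve, best = gm20_fit
        m = MethodSpec("one_parameter")
        g1 = confidence_grid(curve, best, ("f", "D_star"), m, n_points=15)
        g2 = confidence_grid(
            curve, best, ("D_star", "f"), m, n_points=15,
            axes=(g1.axes[1], g1.axes[0]),
        )
        np.testing.assert_allclose(g2.probability, g1.probability.T, rtol=1e-10)

    def test_noiseless_curve_raises_degenerate(self, tumor_curve):
        best = iv.fit_three_parameter(tumor_curve)
        with pytest.raises(DegenerateSurfaceError):
            confidence_grid(
                curve=tumor_curve, best_fit=best, pair=("f", "D_star"),
                method=MethodSpec("three_parameter"), n_points=5,
            )

    def test_dstar_elongation_at_low_snr(self):
        # heavy noise leaves D* far less constrained than f: across fixed
        # noise realizations the 95% region's relative extent along D*
        # typically exceeds twice that along f
        ratios = []
        cfg = iv.SimulationConfig(
            model_params=iv.GM_PARAMS, snr_levels=(20.0,), n_iterations=40, seed=11
        )
        for rec in iv.generate_ensemble(cfg):
            best = iv.fit_one_parameter(rec.curve)
            if best.outlier or best.rss <= 0:
                continue
            grid = confidence_grid(
                rec.curve, best, ("f", "D_star"),
                MethodSpec("one_parameter"), n_points=31,
            )
            inside = grid.probability <= 0.95
            fv = grid.axes[0][inside.any(axis=1)]
            dv = grid.axes[1][inside.any(axis=0)]
            if fv.size == 0 or dv.size == 0:
                continue
            ext_f = (fv.max() - fv.min()) / abs(grid.best_fit.f)
            ext_d = (dv.max() - dv.min()) / abs(grid.best_fit.D_star)
            if ext_f > 0:
                ratios.append(ext_d / ext_f)
        assert len(ratios) >= 10
        assert np.median(ratios) > 2.0


class TestMinimaCensus:
    def test_noiseless_tumor_single_minimum_at_truth(self, tumor_curve):
        census = minima_census(
            tumor_curve, MethodSpec("three_parameter"), truth=iv.TUMOR_PARAMS
        )
        assert census.count == 1
        sol = census.solutions[0].params
        assert sol.D == pytest.approx(iv.TUMOR_PARAMS.D, rel=1e-4)
        assert sol.D_star == pytest.approx(iv.TUMOR_PARAMS.D_star, rel=1e-4)
        assert sol.f == pytest.approx(iv.TUMOR_PARAMS.f, rel=1e-4)
        assert census.global_minimum_correct

    def test_start_grid_spans_bounds_interior(self):
        m = MethodSpec("three_parameter")
        starts = default_start_grid(m)
        assert len(starts) == 27
        arr = np.asarray(starts)
        for k, p in enumerate(("D", "D_star", "f")):
            lb, ub = m.bounds[p]
            assert np.all(arr[:, k] > lb) and np.all(arr[:, k] < ub)
        assert len(default_start_grid(MethodSpec("one_parameter"))) == 3

    def test_count_non_increasing_in_merge_tolerance(self):
        # a noisy realization known to show two distinct interior minima
        # at the default tolerance
        curve = noisy_curve(iv.TUMOR_PARAMS, 60, seed=1, n=26)[25]
        m = MethodSpec("three_parameter")
        counts = [
            minima_census(curve, m, merge_tol=tol).count
            for tol in (1e-4, 1e-3, 1e-2, 1e-1)
        ]
        assert counts[1] > 1  # genuinely multi-minimum at the default tol
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_census_on_flat_curve(self, scheme):
        flat = iv.SignalCurve(scheme, np.ones(len(scheme)))
        with pytest.raises(EmptyCensusError):
            minima_census(flat, MethodSpec("three_parameter"))

    def test_high_snr_limit_single_minimum_all_methods(self, gm_curve, tumor_curve):
        # vanishing noise: one minimum per cascade on both models
        for curve in (gm_curve, tumor_curve):
            for mid in ("one_parameter", "two_parameter", "three_parameter"):
                census = minima_census(curve, MethodSpec(mid))
                assert census.count == 1
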