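"""Series interpolation, plateau detection, and correlation analysis."""

import numpy as np
import pandas as pd
import pytest

from plantrecon.image_metrics import Raster, ToyBackbone
from plantrecon.synthetic_fixtures import generate_training_curve
from plantrecon.training_monitor import (
    MetricSeries,
    PlateauConfig,
    PlateauResult,
    build_series,
    correlation_report,
    detect_plateau,
    interpolate_series,
    load_series,
    pearson_correlation,
    recommend_stop,
    save_series,
)


def brute_force_plateau(values, theta, c):
    """Scan every window: first i with c consecutive sub-theta diffs."""
    diffs = np.abs(np.diff(values))
    for i in range(len(diffs) - c + 1):
        if np.all(diffs[i:i + c] < theta):
            return i
    return None


class TestMetricSeries:
    def test_rejects_unsorted_iterations(self):
        with pytest.raises(ValueError):
            MetricSeries([10, 5], [1.0, 2.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            MetricSeries([1, 2, 3], [1.0, 2.0])

    def test_csv_round_trip(self, tmp_path):
        s = MetricSeries([1000, 2000, 4000], [0.5, 0.3, 0.2])
        save_series(s, tmp_path / "s.csv")
        back = load_series(tmp_path / "s.csv")
        assert np.array_equal(back.iterations, s.iterations)
        assert np.allclose(back.values, s.values)

    def test_csv_missing_column(self, tmp_path):
        (tmp_path / "bad.csv").write_text("iteration,lpips\n1,0.5\n")
        with pytest.raises(ValueError, match="value"):
            load_series(tmp_path / "bad.csv")


class TestInterpolation:
    def test_linear_midpoint(self):
        s = MetricSeries([0, 10], [1.0, 0.0])
        out = interpolate_series(s, PlateauConfig(granularity=11, total_iterations=10))
        assert out.values[5] == pytest.approx(0.5)
        assert out.values[0] == 1.0 and out.values[-1] == 0.0

    def test_hold_rule_beyond_last_checkpoint(self):
        s = MetricSeries([0, 10], [1.0, 0.4])
        out = interpolate_series(s, PlateauConfig(granularity=21, total_iterations=20))
        assert np.all(out.values[out.iterations > 10] == 0.4)

    def test_passes_through_checkpoints_geometric_spacing(self):
        iters = [1000, 2000, 4000, 8000, 16000, 32000]
        vals = [1.0 / i for i in iters]
        s = MetricSeries(iters, vals)
        cfg = PlateauConfig(granularity=3101, total_iterations=32000)
        out = interpolate_series(s, cfg)
        # grid step 10: every checkpoint lands exactly on a grid point
        for it, v in zip(iters, vals):
            idx = np.where(out.iterations == it)[0][0]
            assert out.values[idx] == pytest.approx(v, rel=1e-12)
        # hand-computed piecewise-linear probes
        probe = np.interp([3000, 12000, 24000], iters, vals)
        for t, expected in zip([3000, 12000, 24000], probe):
            idx = np.where(out.iterations == t)[0][0]
            assert out.values[idx] == pytest.approx(expected, rel=1e-12)

    def test_monotone_between_sources(self):
        s = MetricSeries([0, 100], [2.0, 1.0])
        out = interpolate_series(s, PlateauConfig(granularity=50, total_iterations=100))
        assert np.all(np.diff(out.values) <= 0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            interpolate_series(MetricSeries([5], [1.0]), PlateauConfig())


class TestPlateauDetection:
    CFG = PlateauConfig(theta=0.01, consistency=6, granularity=100,
                        total_iterations=100)

    def test_steep_linear_series_not_found(self):
        theta = 0.01
        vals = np.arange(50) * (2 * theta)
        s = MetricSeries(np.arange(50), vals)
        res = detect_plateau(s, PlateauConfig(theta=theta, consistency=6))
        assert not res.found
        assert res.recommended_iteration == 49

    def test_constant_series_plateau_at_start(self):
        s = MetricSeries(np.arange(20), np.full(20, 0.3))
        res = detect_plateau(s, self.CFG)
        assert res.found and res.plateau_index == 0
        assert res.recommended_iteration == 6  # grid[C]

    def test_constructed_decay_window_position(self):
        """diffs [10t, 8t, 4t, 2t, t/2 x many] with C=6 -> plateau index 4."""
        theta = 0.005
        diffs = [10, 8, 4, 2] + [0.5] * 10
        vals = np.concatenate([[1.0], 1.0 - np.cumsum(np.array(diffs) * theta)])
        s = MetricSeries(np.arange(len(vals)), vals)
        res = detect_plateau(s, PlateauConfig(theta=theta, consistency=6))
        assert res.found and res.plateau_index == 4
        assert res.recommended_iteration == 10

    def test_first_window_matches_brute_force_scan(self, rng):
        """Minimality against the exhaustive window scan, 100 random cases."""
        for _ in range(100):
            n = int(rng.integers(10, 120))
            vals = np.cumsum(rng.normal(0, 0.01, n))
            theta = float(rng.uniform(0.002, 0.03))
            c = int(rng.integers(1, min(8, n - 1)))
            cfg = PlateauConfig(theta=theta, consistency=c)
            expected = brute_force_plateau(vals, theta, c)
            res = detect_plateau(MetricSeries(np.arange(n), vals), cfg)
            if expected is None:
                assert not res.found
            else:
                assert res.found and res.plateau_index == expected

    def test_shift_and_negate_invariance(self, rng):
        vals = np.cumsum(rng.normal(0, 0.01, 60))
        s = MetricSeries(np.arange(60), vals)
        cfg = PlateauConfig(theta=0.008, consistency=4)
        base = detect_plateau(s, cfg)
        shifted = detect_plateau(MetricSeries(np.arange(60), vals + 5.0), cfg)
        negated = detect_plateau(MetricSeries(np.arange(60), -vals), cfg)
        assert base == shifted == negated

    def test_series_too_short(self):
        with pytest.raises(ValueError):
            detect_plateau(MetricSeries([0, 1], [0.0, 0.0]),
                           PlateauConfig(consistency=6))


class TestPearson:
    def test_perfect_correlation(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_half_case(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_matches_numpy_corrcoef(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        assert pearson_correlation(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1],
                                                          rel=1e-12)


class TestCorrelationReport:
    def test_affine_lpips_f1_relation(self, rng):
        f1 = rng.uniform(20, 90, 12)
        table = pd.DataFrame({"lpips": 1 - f1 / 100, "f1": f1,
                              "psnr": rng.normal(20, 3, 12)})
        mat = correlation_report(table)
        assert mat.loc["lpips", "f1"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_entries_match_pairwise_calls(self, rng):
        table = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        mat = correlation_report(table)
        for x in table.columns:
            for y in table.columns:
                if x != y:
                    assert mat.loc[x, y] == pytest.approx(
                        pearson_correlation(table[x], table[y]))

    def test_constant_column_rejected(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlation_report(table)


class TestRecommendStop:
    CFG = PlateauConfig(theta=0.005, consistency=6, granularity=1000,
                        total_iterations=60000)

    def test_constant_series_recommends_early(self):
        s = MetricSeries([1000, 30000, 60000], [0.2, 0.2, 0.2])
        iteration, res = recommend_stop(s, self.CFG)
        assert res.found
        # confirmation after C grid steps from the start of the grid
        grid_step = (60000 - 1000) / 999
        assert iteration <= 1000 + 7 * grid_step

    def test_engineered_plateau_confirmed_near_target(self):
        series = generate_training_curve(20000, noise_sigma=0.0)
        iteration, res = recommend_stop(series, self.CFG)
        assert res.found
        interp = interpolate_series(series, self.CFG)
        expected_idx = brute_force_plateau(interp.values, self.CFG.theta,
                                           self.CFG.consistency)
        expected_iter = interp.iterations[expected_idx + self.CFG.consistency]
        grid_step = (60000 - series.iterations[0]) / 999
        assert abs(iteration - expected_iter) <= grid_step

    def test_steep_series_recommends_total(self):
        s = MetricSeries([0, 30000, 60000], [10.0, 5.0, 0.0])
        iteration, res = recommend_stop(s, self.CFG)
        assert not res.found
        assert iteration == 60000

    def test_smaller_theta_never_recommends_earlier(self):
        series = generate_training_curve(25000, noise_sigma=0.0)
        recs = []
        for theta in (0.02, 0.01, 0.005, 0.002):
            cfg = PlateauConfig(theta=theta, consistency=6, granularity=1000,
                                total_iterations=60000)
            recs.append(recommend_stop(series, cfg)[0])
        assert all(a <= b for a, b in zip(recs, recs[1:]))


class TestBuildSeries:
    @staticmethod
    def backbone():
        def feat(r):
            v = float(r.pixels[0, 0]) / 255.0
            return np.array([np.cos(v), np.sin(v)]).reshape(1, 1, 2)
        return ToyBackbone([feat], [np.array([0.5, 0.5])])

    def test_identical_renders_give_zero_series(self):
        val = [Raster(np.full((4, 4), 50.0))]
        ckpts = [(1000, val), (2000, val)]
        s = build_series(ckpts, val, self.backbone())
        assert np.allclose(s.values, 0.0)

    def test_unsorted_checkpoints_sorted_and_mean_correct(self):
        from plantrecon.image_metrics import lpips

        backbone = self.backbone()
        val = [Raster(np.full((4, 4), 0.0)), Raster(np.full((4, 4), 128.0))]
        r1 = [Raster(np.full((4, 4), 64.0)), Raster(np.full((4, 4), 128.0))]
        r2 = [Raster(np.full((4, 4), 255.0)), Raster(np.full((4, 4), 10.0))]
        s = build_series([(5000, r2), (1000, r1)], val, backbone)
        assert list(s.iterations) == [1000, 5000]
        expected1 = np.mean([lpips(a, b, backbone) for a, b in zip(r1, val)])
        assert s.values[0] == pytest.approx(expected1, rel=1e-12)

    def test_duplicate_iterations_rejected(self):
        val = [Raster(np.zeros((4, 4)))]
        with pytest.raises(ValueError, match="duplicate"):
            build_series([(1000, val), (1000, val)], val, self.backbone())

    def test_pairing_failure_rejected(self):
        val = [Raster(np.zeros((4, 4))), Raster(np.zeros((4, 4)))]
        with pytest.raises(ValueError, match="renders"):
            build_series([(1000, val[:1]), (2000, val)], val, self.backbone())
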