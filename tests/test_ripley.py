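"""Ripley's K estimators, difference curves, and permutation envelopes."""

import numpy as np
import pytest

from cachescape.data import Stage
from cachescape.ripley import (
    PointPattern,
    SpatialError,
    Window,
    _isotropic_circle_fraction,
    default_r_grid,
    k_difference,
    k_estimate,
    random_labeling_envelope,
    run_spatial_analysis,
)
from cachescape.simulate import (
    ClusterSpec,
    SimulationConfig,
    StageRates,
    StratumDesign,
    simulate_study,
)

W100 = Window(0, 0, 100, 100)


def brute_force_k(points: np.ndarray, area: float, r_grid: np.ndarray) -> np.ndarray:
    """Uncorrected K̂ by the literal double loop over ordered pairs."""
    n = len(points)
    out = np.zeros(len(r_grid))
    for ridx, r in enumerate(r_grid):
        s = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(points[i] - points[j])) <= r:
                    s += 1
        out[ridx] = area * s / (n * (n - 1))
    return out


class TestKEstimate:
    def test_two_point_hand_value_uncorrected(self):
        pts = np.array([[10.0, 10.0], [10.0, 15.0]])  # distance 5
        k = k_estimate(pts, W100, np.array([10.0]), correction="none")
        assert k.k_values[0] == pytest.approx(10_000.0)

    def test_two_point_hand_value_translation(self):
        # distance 5 with offsets dx=3, dy=4: weight |W|/((100-3)(100-4)) per
        # ordered pair, K = |W|/(2*1) * 2 * |W|/(97*96)
        pts = np.array([[10.0, 10.0], [13.0, 14.0]])
        k = k_estimate(pts, W100, np.array([10.0]), correction="translation")
        assert k.k_values[0] == pytest.approx(10_000.0**2 / (97.0 * 96.0))

    def test_r_zero_gives_zero(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 2))
        k = k_estimate(pts, W100, np.array([0.0, 5.0]), correction="translation")
        assert k.k_values[0] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_uncorrected_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        pts = rng.uniform(0, 100, (n, 2))
        r_grid = np.linspace(0, 40, 17)
        fast = k_estimate(pts, W100, r_grid, correction="none").k_values
        slow = brute_force_k(pts, W100.area, r_grid)
        np.testing.assert_allclose(fast, slow, rtol=0, atol=0)

    def test_k_nondecreasing(self):
        pts = np.random.default_rng(3).uniform(0, 100, (80, 2))
        for corr in ("none", "translation", "isotropic"):
            k = k_estimate(pts, W100, np.linspace(0, 25, 64), corr)
            assert (np.diff(k.k_values) >= 0).all()

    def test_translation_invariance_under_shift_and_axis_swap(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, (60, 2))
        r_grid = np.linspace(0, 25, 32)
        base = k_estimate(pts, W100, r_grid, "translation").k_values
        shifted = k_estimate(pts + [37.0, -12.0], Window(37, -12, 100, 100),
                             r_grid, "translation").k_values
        swapped = k_estimate(pts[:, ::-1], W100, r_grid, "translation").k_values
        np.testing.assert_allclose(shifted, base, rtol=1e-12)
        np.testing.assert_allclose(swapped, base, rtol=1e-12)

    def test_insufficient_points_error(self):
        with pytest.raises(SpatialError, match="at least 2"):
            k_estimate(np.array([[1.0, 1.0]]), W100, np.array([5.0]))

    def test_r_beyond_validity_bound_error(self):
        pts = np.random.default_rng(0).uniform(0, 100, (10, 2))
        with pytest.raises(SpatialError, match="validity bound"):
            k_estimate(pts, W100, np.array([150.0]), "translation")

    def test_isotropic_circle_fractions(self):
        # interior point: full circle; corner: quarter; edge midpoint: half
        xy = np.array([[50.0, 50.0], [0.0, 0.0], [50.0, 0.0]])
        frac = _isotropic_circle_fraction(xy, W100, np.array([10.0, 10.0, 10.0]))
        np.testing.assert_allclose(frac, [1.0, 0.25, 0.5])

    @pytest.mark.parametrize("correction", ["translation", "isotropic"])
    def test_csr_mean_near_pi_r_squared(self, correction):
        r_grid = np.array([5.0, 10.0, 20.0])
        vals = [
            k_estimate(np.random.default_rng(s).uniform(0, 100, (300, 2)),
                       W100, r_grid, correction).k_values
            for s in range(40)
        ]
        mean = np.mean(vals, axis=0)
        se = np.std(vals, axis=0, ddof=1) / np.sqrt(len(vals))
        assert (np.abs(mean - np.pi * r_grid**2) < 3 * se).all()


class TestKDifference:
    def test_antisymmetry_under_mark_swap(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (60, 2))
        marks = rng.random(60) < 0.4
        r_grid = np.linspace(0, 20, 16)
        d1 = k_difference(PointPattern(pts, marks, W100), r_grid)
        d2 = k_difference(PointPattern(pts, ~marks, W100), r_grid)
        np.testing.assert_allclose(d2, -d1, rtol=1e-12)

    def test_identical_jittered_classes_give_near_zero(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(10, 90, (50, 2))
        pts = np.vstack([base, base + rng.normal(0, 1e-4, base.shape)])
        marks = np.repeat([True, False], 50)
        diff = k_difference(PointPattern(pts, marks, W100), np.linspace(0, 20, 16))
        assert np.abs(diff).max() < 1e-3 * np.pi * 20**2

    def test_packed_successes_give_positive_difference(self):
        rng = np.random.default_rng(6)
        cluster = rng.uniform(40, 60, (30, 2))      # successes in one 20 m patch
        csr = rng.uniform(0, 100, (30, 2))          # failures spread out
        pts = np.vstack([cluster, csr])
        marks = np.repeat([True, False], 30)
        diff = k_difference(PointPattern(pts, marks, W100), np.array([10.0, 20.0]))
        assert (diff > 0).all()

    def test_sparse_mark_class_error(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 2))
        marks = np.zeros(20, bool)
        marks[0] = True  # a lone success: no within-class pairs
        with pytest.raises(SpatialError, match=">= 2 points"):
            k_difference(PointPattern(pts, marks, W100), np.array([10.0]))


class TestEnvelope:
    def _pattern(self, seed=1, n=80):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (n, 2))
        marks = np.zeros(n, bool)
        marks[rng.choice(n, n // 2, replace=False)] = True
        return PointPattern(pts, marks, W100)

    def test_seeded_reproducibility(self):
        pat = self._pattern()
        e1 = random_labeling_envelope(pat, n_sim=99, seed=7)
        e2 = random_labeling_envelope(pat, n_sim=99, seed=7)
        np.testing.assert_array_equal(e1.env_low, e2.env_low)
        np.testing.assert_array_equal(e1.env_high, e2.env_high)
        assert e1.departures == e2.departures

    def test_envelope_monotone_in_level(self):
        pat = self._pattern()
        e95 = random_labeling_envelope(pat, n_sim=199, level=0.95, seed=3)
        e99 = random_labeling_envelope(pat, n_sim=199, level=0.99, seed=3)
        assert (e99.env_low <= e95.env_low).all()
        assert (e99.env_high >= e95.env_high).all()

    def test_too_few_simulations_error(self):
        with pytest.raises(SpatialError, match="at least 39"):
            random_labeling_envelope(self._pattern(), n_sim=38, level=0.95)

    def test_departures_are_exactly_the_exit_intervals(self):
        pat = self._pattern(seed=11)
        env = random_labeling_envelope(pat, n_sim=99, seed=11)
        above = env.observed_diff > env.env_high
        below = env.observed_diff < env.env_low
        flagged = np.zeros_like(above)
        for lo, hi, _ in env.departures:
            flagged |= (env.r_grid >= lo) & (env.r_grid <= hi)
        assert np.array_equal(flagged, above | below)

    def test_ordered_bounds(self):
        env = random_labeling_envelope(self._pattern(), n_sim=99, seed=1)
        assert (env.env_low <= env.env_high).all()


class TestRunSpatialAnalysis:
    def _two_zone_config(self, seed):
        design, probs, windows = [], {}, {}
        for zone in ("treeline", "subalpine"):
            design.append(StratumDesign("a", zone, "open", 150))
            probs[("a", zone, "open")] = StageRates(0.5, 0.5, 0.5, 0.1)
            windows[("a", zone)] = (300.0, 300.0)
        return SimulationConfig(seed=seed, design=design, windows=windows,
                                stage_probabilities=probs, p_located=1.0)

    def test_groups_analysed_and_seeded_identically(self):
        recs = simulate_study(self._two_zone_config(0))
        r1 = run_spatial_analysis(recs, Stage.PILFERAGE, n_sim=99, seed=5)
        r2 = run_spatial_analysis(recs, Stage.PILFERAGE, n_sim=99, seed=5)
        assert len(r1) == 2
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.observed_diff, b.observed_diff)
            assert a.departures == b.departures
            assert dict(a.group)["study_area"] == "a"

    def test_degenerate_group_skipped_with_log(self, caplog):
        cfg = SimulationConfig(
            seed=1,
            design=[StratumDesign("a", "treeline", "open", 60),
                    StratumDesign("a", "subalpine", "open", 60)],
            windows={("a", "treeline"): (300.0, 300.0),
                     ("a", "subalpine"): (300.0, 300.0)},
            stage_probabilities={
                # survival certain at treeline: no failures to compare against
                ("a", "treeline", "open"): StageRates(0.0, 1.0, 1.0, 0.0),
                ("a", "subalpine", "open"): StageRates(0.0, 1.0, 0.5, 0.0),
            },
            p_located=1.0,
        )
        recs = simulate_study(cfg)
        results = run_spatial_analysis(recs, Stage.SURVIVAL, n_sim=99, seed=2)
        assert len(results) == 1
        assert dict(results[0].group)["elevation_zone"] == "subalpine"
        assert "skipped" in caplog.text

    def test_clustered_zone_flags_departure_other_zone_mostly_not(self):
        """Clustered pilferage injected at treeline only: the treeline group
        reports a success-clustered departure in a seeded majority of runs."""
        hits_tl, hits_sub = 0, 0
        n_runs = 10
        for s in range(n_runs):
            design = [StratumDesign("a", "treeline", "open", 150),
                      StratumDesign("a", "subalpine", "open", 150)]
            recs_tl = simulate_study(SimulationConfig(
                seed=s, design=design[:1],
                windows={("a", "treeline"): (300.0, 300.0)},
                stage_probabilities={("a", "treeline", "open"): StageRates(0.5, 0.5, 0.5, 0.1)},
                p_located=1.0,
                clustering={"pilferage": ClusterSpec(2, 50.0, 0.9, 0.1)},
            ))
            recs_sub = simulate_study(SimulationConfig(
                seed=1000 + s, design=design[1:],
                windows={("a", "subalpine"): (300.0, 300.0)},
                stage_probabilities={("a", "subalpine", "open"): StageRates(0.5, 0.5, 0.5, 0.1)},
                p_located=1.0,
            ))
            results = run_spatial_analysis(recs_tl + recs_sub, Stage.PILFERAGE,
                                           n_sim=199, seed=s)
            by_zone = {dict(r.group)["elevation_zone"]: r for r in results}
            if any(d == "success-clustered" for *_, d in by_zone["treeline"].departures):
                hits_tl += 1
            if any(d == "success-clustered" for *_, d in by_zone["subalpine"].departures):
                hits_sub += 1
        assert hits_tl >= 7
        assert hits_sub <= 5
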