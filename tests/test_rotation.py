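import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rotortrack as rt
from rotortrack.phase import PSDetection
from rotortrack.rotation import (
    EdgeDistanceSeries,
    EdgeTrace,
    RotationConfig,
    build_distance_series,
    count_rotations,
    detect_edge,
    edge_distance,
    quantify_trajectory,
)


def trace(pixels, frame=0):
    return EdgeTrace(frame=frame, pixels=np.asarray(pixels, float))


def brute_force_largest_sv(diff):
    """Independent oracle: sqrt of the largest eigenvalue of D^T D."""
    g = diff.T @ diff
    return float(np.sqrt(np.linalg.eigvalsh(g).max()))


class TestRotationConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            RotationConfig(L=4)
        with pytest.raises(ValueError):
            RotationConfig(min_prominence=1.5)
        with pytest.raises(ValueError):
            RotationConfig(metric="cosine")


class TestDetectEdge:
    def test_smooth_ramp_has_no_edge(self):
        # linear phase ramp with no wrap inside the box
        y, x = np.mgrid[0:21, 0:21]
        frame = 0.05 * x + 0.02 * y - 1.0
        ps = PSDetection(frame=0, x=10, y=10, chirality=1)
        assert detect_edge(frame, ps, RotationConfig(L=11)).is_empty

    def test_vertical_wrap_step_found_on_column(self):
        frame = np.full((21, 21), np.pi - 0.01)
        frame[:, 11:] = -np.pi + 0.01
        ps = PSDetection(frame=0, x=10, y=10, chirality=1)
        edge = detect_edge(frame, ps, RotationConfig(L=11))
        assert not edge.is_empty
        assert np.all(np.abs(edge.pixels[:, 0] - 10.5) <= 1.5)

    def test_spiral_edge_connected_and_grows_with_L(self, spiral_phase):
        frame = spiral_phase.phase[0]
        ps = rt.detect_ps(frame)[0]
        lengths = []
        for L in (7, 11, 15, 19):
            edge = detect_edge(frame, ps, RotationConfig(L=L))
            assert not edge.is_empty
            # indexed by distance: radius of entry k is about k+1
            radii = np.hypot(edge.pixels[:, 0] - ps.x, edge.pixels[:, 1] - ps.y)
            assert np.all(np.diff(radii) > 0)
            lengths.append(len(edge))
        assert lengths == sorted(lengths)
        assert lengths[-1] > lengths[0]

    def test_clipped_flag_at_grid_boundary(self, spiral_phase):
        frame = spiral_phase.phase[0]
        ps = PSDetection(frame=0, x=2, y=2, chirality=1)
        assert detect_edge(frame, ps, RotationConfig(L=11)).clipped


class TestEdgeDistance:
    def test_identical_edges_zero(self):
        a = trace([(1, 2), (3, 4), (5, 6)])
        assert edge_distance(a, a) == 0.0

    def test_translated_edge_example(self):
        a = trace([(0, 0), (1, 0), (2, 0), (3, 0)])
        b = trace([(3, 0), (4, 0), (5, 0), (6, 0)])
        assert edge_distance(a, b) == pytest.approx(6.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = trace(rng.integers(0, 20, (8, 2)))
        b = trace(rng.integers(0, 20, (8, 2)))
        assert edge_distance(a, b) == pytest.approx(edge_distance(b, a))

    def test_truncation_keeps_pixels_nearest_ps(self):
        a = trace([(0, 0), (1, 0)])
        b = trace([(0, 0), (1, 0), (50, 50)])
        assert edge_distance(a, b) == 0.0

    def test_empty_edge_gives_nan(self):
        a = trace([(0, 0)])
        assert np.isnan(edge_distance(a, trace(np.empty((0, 2)))))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 12)
            a = trace(rng.uniform(0, 30, (n, 2)))
            b = trace(rng.uniform(0, 30, (n, 2)))
            expected = brute_force_largest_sv(a.pixels - b.pixels)
            got = edge_distance(a, b)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_alternate_metrics_are_nonnegative_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = trace(rng.uniform(0, 10, (6, 2)))
        b = trace(rng.uniform(0, 10, (9, 2)))
        for metric in ("svd", "mean", "hausdorff"):
            d_ab = edge_distance(a, b, metric=metric)
            assert d_ab >= 0
            assert d_ab == pytest.approx(edge_distance(b, a, metric=metric))


class TestCountRotations:
    cfg = RotationConfig()

    def _series(self, values):
        values = np.asarray(values, float)
        return EdgeDistanceSeries(
            frames=np.arange(len(values)), values=values, reference_index=0
        )

    def test_monotone_series_has_no_rotation(self):
        assert count_rotations(self._series([0, 1, 2, 3, 4, 5]), self.cfg) == 0

    def test_three_returns_counted(self):
        s = self._series([0, 5, 0.4, 5, 0.2, 5, 0.3])
        assert count_rotations(s, self.cfg) == 3
        assert list(s.minima_frames) == [2, 4, 6]

    def test_reference_start_not_counted(self):
        assert count_rotations(self._series([0, 5, 5, 5, 5]), self.cfg) == 0

    def test_shallow_wiggles_rejected_by_prominence(self):
        s = self._series([0, 5, 4.8, 5, 4.9, 5, 0.2, 5])
        assert count_rotations(s, self.cfg) == 1

    def test_long_gap_splits_series(self):
        nan = np.nan
        vals = [0, 5, 0.2, 5] + [nan] * 10 + [5, 0.2, 5, 0.1]
        n = count_rotations(self._series(vals), self.cfg)
        assert n == 3  # one before the gap, two after; none bridging it

    def test_all_missing_series(self):
        assert count_rotations(self._series([np.nan] * 5), self.cfg) == 0


class TestQuantifyTrajectory:
    def test_rejects_too_short_trajectory(self, spiral_phase):
        tr = rt.PSTrajectory(id=0, detections=[PSDetection(0, 20, 20, 1)])
        with pytest.raises(ValueError):
            quantify_trajectory(tr, spiral_phase)

    def test_stationary_rotor_recovers_count_and_zero_displacement(self, small_spec, spiral_phase):
        dets = rt.detect_ps_movie(spiral_phase)
        trajs = rt.link_ps([d for fr in dets for d in fr], rt.TrackingConfig(),
                           sampling_rate=small_spec.sampling_rate)
        q = quantify_trajectory(max(trajs, key=len), spiral_phase)
        assert q.p_d == (0, 0)
        assert abs(q.n_rotations - small_spec.true_rotations) <= 1
        assert len(q.path) == len(q.trajectory)
        assert q.reliable

    def test_drifting_rotor_displacement(self):
        # tip drifts 8 px in x, 7 in y over a stable 10-rotation run
        n = 1000
        path = np.column_stack([
            20.3 + 8.0 * np.arange(n) / (n - 1),
            20.3 + 7.0 * np.arange(n) / (n - 1),
        ])
        spec = rt.SpiralSpec(grid_height=48, grid_width=48, duration=1000.0,
                             rotation_period=100.0, tip_path=path)
        phase = rt.make_phase_spiral(spec)
        dets = [d for fr in rt.detect_ps_movie(phase) for d in fr]
        trajs = rt.link_ps(dets, rt.TrackingConfig(), sampling_rate=1000.0)
        q = quantify_trajectory(max(trajs, key=len), phase)
        assert q.p_d == (8, 7)
        assert abs(q.n_rotations - 10) <= 1

    def test_mostly_missing_edges_flagged_unreliable(self):
        # flat phase away from any singularity: no edges anywhere
        phase = rt.PhaseMovie(
            phase=np.zeros((10, 20, 20)), sampling_rate=1000.0, mask=np.ones((20, 20), bool)
        )
        tr = rt.PSTrajectory(
            id=0, detections=[PSDetection(t, 10, 10, 1) for t in range(10)]
        )
        q = quantify_trajectory(tr, phase)
        assert not q.reliable
        assert q.n_rotations == 0


class TestLengthNormalisation:
    def test_series_insensitive_to_truncation_length(self):
        # same rotated ray, one frame detected shorter: normalised values agree
        def ray(angle, n):
            return trace([(k * np.cos(angle), k * np.sin(angle)) for k in range(1, n + 1)])

        ref = ray(0.0, 5)
        full = ray(1.0, 5)
        short = ray(1.0, 3)
        series = build_distance_series([ref, full, short])
        assert series.values[1] == pytest.approx(series.values[2], rel=1e-9)
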