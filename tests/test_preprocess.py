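import numpy as np
import pytest

import rotortrack as rt
from rotortrack.preprocess import (
    PreprocessConfig,
    VoltageMovie,
    normalize,
    preprocess,
    remove_baseline,
    spatial_bin,
    temporal_filter,
)


def movie_from(frames, rate=1000.0, mask=None):
    return VoltageMovie(frames=np.asarray(frames, float), sampling_rate=rate, mask=mask)


class TestVoltageMovie:
    def test_rejects_short_movie(self):
        with pytest.raises(ValueError):
            movie_from(np.zeros((1, 4, 4)))

    def test_rejects_mask_mismatch(self):
        with pytest.raises(ValueError):
            movie_from(np.zeros((3, 4, 4)), mask=np.ones((5, 5), bool))


class TestSpatialBin:
    def test_bin_one_is_identity(self):
        m = movie_from(np.random.default_rng(0).normal(size=(3, 8, 8)))
        out = spatial_bin(m, 1)
        assert np.array_equal(out.frames, m.frames)

    def test_even_bin_rejected(self):
        with pytest.raises(ValueError):
            spatial_bin(movie_from(np.zeros((2, 8, 8))), 4)

    def test_constant_frame_unchanged(self):
        m = movie_from(np.full((2, 9, 9), 3.5))
        assert np.allclose(spatial_bin(m, 3).frames, 3.5)

    def test_single_bright_pixel_spreads_to_ninth(self):
        frames = np.zeros((2, 9, 9))
        frames[:, 4, 4] = 9.0
        out = spatial_bin(movie_from(frames), 3)
        assert np.allclose(out.frames[0, 3:6, 3:6], 1.0)
        assert np.allclose(out.frames[0, 0, 0], 0.0)

    def test_mask_pixels_gain_no_signal_from_outside(self):
        # bright non-tissue pixel must not leak into the tissue mean
        frames = np.zeros((2, 9, 9))
        frames[:, 4, 4] = 100.0
        mask = np.ones((9, 9), bool)
        mask[4, 4] = False
        out = spatial_bin(movie_from(frames, mask=mask), 3)
        assert np.allclose(out.frames[0][mask], 0.0)


class TestTemporalFilter:
    def test_rejects_cutoff_at_nyquist(self):
        with pytest.raises(ValueError):
            temporal_filter(movie_from(np.zeros((100, 2, 2))), 500.0)

    def test_dc_gain_unity(self):
        m = movie_from(np.full((200, 2, 2), 7.0))
        assert np.allclose(temporal_filter(m, 100.0).frames, 7.0, atol=1e-8)

    def test_stopband_attenuation_at_least_20db(self):
        t = np.arange(1000) / 1000.0
        sig = np.sin(2 * np.pi * 400 * t)  # far above the 50 Hz cutoff
        frames = np.tile(sig[:, None, None], (1, 2, 2))
        out = temporal_filter(movie_from(frames), 50.0)
        mid = slice(100, 900)
        gain = out.frames[mid, 0, 0].std() / sig[mid].std()
        assert gain < 0.1

    def test_passband_idempotence(self):
        t = np.arange(1000) / 1000.0
        sig = np.sin(2 * np.pi * 10 * t)
        frames = np.tile(sig[:, None, None], (1, 2, 2))
        once = temporal_filter(movie_from(frames), 100.0)
        twice = temporal_filter(once, 100.0)
        assert np.allclose(once.frames, twice.frames, atol=1e-3)


class TestRemoveBaseline:
    def test_linear_ramp_removed(self):
        t = np.linspace(0, 1, 500)
        frames = np.tile((5 * t)[:, None, None], (1, 2, 2))
        out = remove_baseline(movie_from(frames))
        slope = np.polyfit(t, out.frames[:, 0, 0], 1)[0]
        assert abs(slope) < 1e-6

    def test_driftfree_sinusoid_preserved(self):
        # polynomial detrending perturbs a 25-cycle sinusoid by a few
        # percent RMS (record-edge effects); it must not do worse
        t = np.arange(1000) / 1000.0
        sig = np.sin(2 * np.pi * 25 * t)
        frames = np.tile(sig[:, None, None], (1, 2, 2))
        out = remove_baseline(movie_from(frames))
        rms = np.sqrt(np.mean((out.frames[:, 0, 0] - sig) ** 2))
        assert rms < 0.05

    def test_sinusoid_recovered_from_ramp(self):
        t = np.arange(1000) / 1000.0
        sig = np.sin(2 * np.pi * 25 * t)
        frames = np.tile((sig + 3 * t)[:, None, None], (1, 2, 2))
        out = remove_baseline(movie_from(frames))
        rms = np.sqrt(np.mean((out.frames[:, 0, 0] - sig) ** 2))
        assert rms < 0.05

    def test_highpass_method(self):
        t = np.arange(2000) / 1000.0
        sig = np.sin(2 * np.pi * 25 * t)
        frames = np.tile((sig + 2 * t)[:, None, None], (1, 2, 2))
        cfg = PreprocessConfig(baseline_method="highpass", baseline_cutoff=2.0)
        out = remove_baseline(movie_from(frames), cfg)
        mid = slice(300, 1700)
        assert np.allclose(out.frames[mid, 0, 0], sig[mid], atol=0.1)


class TestNormalize:
    def test_affine_map_to_unit_interval(self):
        frames = np.array([2.0, 4.0, 6.0])[:, None, None] * np.ones((1, 2, 2))
        out = normalize(movie_from(frames))
        assert np.allclose(out.frames[:, 0, 0], [0.0, 0.5, 1.0])

    def test_unit_trace_unchanged(self):
        frames = np.array([0.0, 0.25, 1.0])[:, None, None] * np.ones((1, 2, 2))
        out = normalize(movie_from(frames))
        assert np.allclose(out.frames, frames)

    def test_constant_pixel_dropped_from_mask(self):
        frames = np.random.default_rng(1).normal(size=(10, 3, 3))
        frames[:, 1, 1] = 2.0
        out = normalize(movie_from(frames))
        assert not out.mask[1, 1]
        assert out.mask.sum() == 8


class TestPipeline:
    def test_pipeline_stability_of_detections(self, small_spec):
        # conditioning a noiseless synthetic movie moves PS detections
        # by at most 1 pixel per frame versus skipping it
        movie = rt.make_voltage_movie(small_spec)
        raw = rt.run_pipeline(movie, skip_preprocess=True)
        conditioned = rt.run_pipeline(movie)
        n = min(len(raw.detections), len(conditioned.detections))
        assert n > 0
        by_frame_raw = {d.frame: d for d in raw.detections}
        moved = []
        for d in conditioned.detections:
            r = by_frame_raw.get(d.frame)
            if r is not None:
                moved.append(max(abs(d.x - r.x), abs(d.y - r.y)))
        assert moved and np.max(moved) <= 1
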