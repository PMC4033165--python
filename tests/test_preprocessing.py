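"""Filtering, centering, artifact exclusion, label shifting, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from percepttrack import preprocessing as pp, synthetic_data as sd
from percepttrack.core import (LABEL_LINE, LABEL_OBJECT, LABEL_UNDEFINED,
                               LINE, OBJECT, Interval, PerceptTimeline)
from percepttrack.errors import InvalidArgumentError, MissingBaselineError


class TestZeroCenter:
    def test_constant_series(self):
        s = np.full((10, 3), 100.0)
        centered, base = pp.zero_center(s)
        np.testing.assert_allclose(centered, 0.0)
        np.testing.assert_allclose(base, 100.0)

    def test_online_mode_uses_stored_baseline(self):
        new = np.array([[103.0]])
        centered, _ = pp.zero_center(new, baseline=np.array([100.0]))
        assert centered[0, 0] == pytest.approx(3.0)

    def test_offline_output_has_zero_mean(self):
        rng = np.random.default_rng(0)
        s = rng.normal(100, 5, (50, 4))
        centered, _ = pp.zero_center(s)
        np.testing.assert_allclose(centered.mean(axis=0), 0.0, atol=1e-10)

    def test_missing_baseline_shape_raises(self):
        with pytest.raises(MissingBaselineError):
            pp.zero_center(np.zeros((5, 3)), baseline=np.zeros(2))


class TestBandpass:
    TR = 2.0
    CFG = pp.FilterConfig(1 / 128, 1 / 16, order=4)

    def _sine(self, freq, n=300):
        t = np.arange(n) * self.TR
        return np.sin(2 * np.pi * freq * t)[:, None]

    def _fft_amplitude(self, x, freq):
        n = x.size
        f = np.fft.rfftfreq(n, d=self.TR)
        spec = np.abs(np.fft.rfft(x)) * 2 / n
        return spec[np.argmin(np.abs(f - freq))]

    def test_passband_sinusoid_preserved(self):
        x = self._sine(1 / 30)
        y = pp.bandpass(x, self.TR, self.CFG)
        assert self._fft_amplitude(y[:, 0], 1 / 30) == pytest.approx(
            self._fft_amplitude(x[:, 0], 1 / 30), rel=0.10)

    def test_dc_removed(self):
        x = np.full((200, 1), 5.0)
        y = pp.bandpass(x, self.TR, self.CFG)
        assert np.abs(y[50:]).max() < 0.05

    def test_stopband_sinusoid_attenuated(self):
        x = self._sine(1 / 4.5)  # above the 1/16 Hz low-pass cut
        y = pp.bandpass(x, self.TR, self.CFG)
        assert self._fft_amplitude(y[:, 0], 1 / 4.5) < \
            0.1 * self._fft_amplitude(x[:, 0], 1 / 4.5)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(120, 1)), rng.normal(size=(120, 1))
        lhs = pp.bandpass(2.0 * x + 3.0 * y, self.TR, self.CFG)
        rhs = 2.0 * pp.bandpass(x, self.TR, self.CFG) + \
            3.0 * pp.bandpass(y, self.TR, self.CFG)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.bandpass(np.zeros((100, 1)), 2.0,
                        pp.FilterConfig(1 / 128, 0.3, order=4))

    def test_causal_streaming_matches_batch(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 3))
        cfg = pp.FilterConfig(1 / 128, 1 / 16, order=2, mode=pp.CAUSAL)
        batch = pp.bandpass(x, self.TR, cfg)
        stream = pp.CausalBandpass(self.TR, cfg, 3)
        out = np.vstack([stream.step(row) for row in x])
        np.testing.assert_allclose(out, batch, atol=1e-12)


class TestExclusion:
    def test_simulated_vessel_voxel_excluded(self):
        tl = sd.simulate_percept_timeline(
            420.0, sd.GammaDwellConfig(5.29, 4.26, min_duration=4.0, seed=6))
        vox = sd.VoxelSpec(grid_shape=(2, 2, 1), object_positive_voxels=[0],
                           object_negative_voxels=[], vessel_voxels=[3],
                           vessel_amplitude=12.0)
        run = sd.simulate_run(tl, vox, sd.NoiseConfig(sigma=0.0,
                                                      drift_amplitude=0.0),
                              tr=2.0)
        retained, report = pp.exclude_high_signal_change_voxels(run.as_matrix())
        assert 3 in report["excluded_indices"]
        assert 0 in retained

    def test_constant_run_keeps_everything(self):
        retained, report = pp.exclude_high_signal_change_voxels(
            np.full((20, 5), 100.0))
        assert report["n_excluded"] == 0
        assert retained.size == 5

    def test_exactly_ten_percent_retained(self):
        # boundary is strict: max deviation exactly at threshold stays in
        s = np.full((10, 1), 100.0)
        s[0, 0] = 110.0 - 1e-9
        base = np.array([100.0])
        retained, _ = pp.exclude_high_signal_change_voxels(s, baseline=base)
        assert 0 in retained
        s[0, 0] = 111.0
        retained, _ = pp.exclude_high_signal_change_voxels(s, baseline=base)
        assert retained.size == 0

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        s = 100 + rng.normal(0, 4, (30, 40))
        first, _ = pp.exclude_high_signal_change_voxels(s)
        second, _ = pp.exclude_high_signal_change_voxels(s[:, first])
        assert second.size == first.size  # all survivors survive again


def _two_state_timeline(durations, first=LINE):
    intervals, t, state = [], 0.0, first
    for d in durations:
        intervals.append(Interval(t, d, state))
        t += d
        state = OBJECT if state == LINE else LINE
    return PerceptTimeline(tuple(intervals), t)


def _brute_force_labels(timeline, tr, n_volumes, delay):
    """Independent oracle: fine-grid occupancy count in each shifted window."""
    dt = 0.001
    labels = np.zeros(n_volumes, dtype=int)
    for k in range(n_volumes):
        a, b = k * tr - delay, (k + 1) * tr - delay
        if a < 0:
            continue
        grid = np.arange(a + dt / 2, b, dt)
        states = [timeline.state_at(t) for t in grid]
        n_obj = sum(s == OBJECT for s in states)
        n_line = len(states) - n_obj
        if n_obj > n_line:
            labels[k] = LABEL_OBJECT
        elif n_line > n_obj:
            labels[k] = LABEL_LINE
        else:  # tie -> state at window start
            labels[k] = LABEL_OBJECT if timeline.state_at(a) == OBJECT \
                else LABEL_LINE
    return labels


class TestLabels:
    def test_tr25_delay5_is_exact_two_volume_shift(self):
        tl = _two_state_timeline([25.0, 25.0, 50.0])
        tr, n = 2.5, 40
        lab = pp.labels_per_volume(tl, tr, n, hrf_delay=5.0)
        unshifted = pp.labels_per_volume(tl, tr, n, hrf_delay=0.0)
        assert (lab[:2] == LABEL_UNDEFINED).all()
        np.testing.assert_array_equal(lab[2:], unshifted[:-2])

    def test_delay_zero_matches_timeline(self):
        tl = _two_state_timeline([10.0, 10.0, 20.0])
        lab = pp.labels_per_volume(tl, 2.0, 20, hrf_delay=0.0)
        expected = [timelinestate(tl, k * 2.0) for k in range(20)]
        np.testing.assert_array_equal(lab, expected)

    def test_tr2_delay5_against_brute_force_oracle(self):
        tl = _two_state_timeline([13.0, 9.0, 17.0, 11.0, 50.0], first=OBJECT)
        tr, n = 2.0, 50
        lab = pp.labels_per_volume(tl, tr, n, hrf_delay=5.0)
        oracle = _brute_force_labels(tl, tr, n, 5.0)
        np.testing.assert_array_equal(lab, oracle)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(4.0, 40.0), min_size=2, max_size=8),
           st.sampled_from([2.0, 2.5]))
    def test_defined_labels_are_reindexed_timeline_states(self, durs, tr):
        # label shifting is pure re-indexing: every defined label equals the
        # timeline state at the center of its shifted window
        tl = _two_state_timeline(durs)
        n = int(tl.total_duration // tr)
        if n < 4:
            return
        lab = pp.labels_per_volume(tl, tr, n, hrf_delay=5.0)
        oracle = _brute_force_labels(tl, tr, n, 5.0)
        np.testing.assert_array_equal(lab, oracle)


def timelinestate(tl, t):
    return LABEL_OBJECT if tl.state_at(t) == OBJECT else LABEL_LINE


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(8, 8, 4))
        np.testing.assert_array_equal(pp.smooth_spatial(v, 0.0), v)

    def test_delta_profile_width_matches_fwhm(self):
        v = np.zeros((41, 41, 41))
        v[20, 20, 20] = 1.0
        out = pp.smooth_spatial(v, fwhm_mm=8.0, voxel_size_mm=2.0)
        profile = out[:, 20, 20]
        half = profile.max() / 2
        # sub-voxel half-maximum crossings by linear interpolation
        x = np.arange(profile.size, dtype=float)
        left = np.interp(half, profile[:21], x[:21])
        right = np.interp(half, profile[20:][::-1], x[20:][::-1])
        width_mm = (right - left) * 2.0
        assert width_mm == pytest.approx(8.0, abs=1.0)  # half a voxel

    def test_interior_delta_mass_preserved(self):
        v = np.zeros((31, 31, 31))
        v[15, 15, 15] = 1.0
        out = pp.smooth_spatial(v, fwhm_mm=6.0, voxel_size_mm=3.0)
        assert out.sum() == pytest.approx(1.0, rel=0.01)
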