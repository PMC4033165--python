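"""Generator correctness: dwell distribution, HRF, run simulation, I/O."""

import numpy as np
import pytest


from percepttrack import synthetic_data as sd
from percepttrack.core import LINE, OBJECT
from percepttrack.errors import InvalidArgumentError


class TestDwellTimes:
    def test_gamma_moments_at_large_n(self):
        # sample mean -> shape*scale, variance -> shape*scale^2 (3 SE bands)
        for shape, scale in [(2.00, 7.51), (5.29, 4.26)]:
            cfg = sd.GammaDwellConfig(shape, scale, seed=1)
            d = sd.sample_dwell_times(50_000, cfg)
            mean, var = shape * scale, shape * scale ** 2
            se_mean = np.sqrt(var / d.size)
            assert abs(d.mean() - mean) < 3 * se_mean
            # SE of the sample variance via the 4th central moment
            mu4 = (3 + 6 / shape) * var ** 2  # gamma excess kurtosis 6/shape
            se_var = np.sqrt((mu4 - var ** 2) / d.size)
            assert abs(d.var(ddof=1) - var) < 3 * se_var

    def test_min_duration_rejection(self):
        cfg = sd.GammaDwellConfig(2.0, 7.51, min_duration=5.0, seed=3)
        d = sd.sample_dwell_times(5000, cfg)
        assert (d >= 5.0).all()

    def test_timeline_mean_dwell_matches_analytic(self):
        cfg = sd.GammaDwellConfig(5.29, 4.26, seed=2)
        d = sd.sample_dwell_times(10_000, cfg)
        se = np.sqrt(5.29 * 4.26 ** 2 / d.size)
        assert abs(d.mean() - 5.29 * 4.26) < 3 * se  # = 22.5 s

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd.GammaDwellConfig(0.0, 4.26)
        with pytest.raises(InvalidArgumentError):
            sd.simulate_percept_timeline(-1.0, sd.GammaDwellConfig(2, 7.5))


class TestTimeline:
    def test_long_dwell_truncates_to_single_interval(self):
        cfg = sd.GammaDwellConfig(100.0, 100.0, seed=0)
        tl = sd.simulate_percept_timeline(420.0, cfg)
        assert len(tl.intervals) == 1
        assert tl.intervals[0].duration == pytest.approx(420.0)

    def test_same_seed_reproduces_timeline(self):
        cfg = sd.GammaDwellConfig(5.29, 4.26, min_duration=4.0, seed=9)
        a = sd.simulate_percept_timeline(420.0, cfg)
        b = sd.simulate_percept_timeline(420.0, cfg)
        assert a == b

    def test_states_alternate_and_cover_duration(self):
        cfg = sd.GammaDwellConfig(2.0, 7.51, min_duration=5.0, seed=4)
        tl = sd.simulate_percept_timeline(420.0, cfg)
        states = tl.states()
        assert all(a != b for a, b in zip(states, states[1:]))
        assert tl.durations().sum() == pytest.approx(420.0)
        assert {LINE, OBJECT} >= set(states)


class TestReportJitter:
    def test_zero_latency_is_identity(self):
        cfg = sd.GammaDwellConfig(5.29, 4.26, min_duration=4.0, seed=8)
        tl = sd.simulate_percept_timeline(420.0, cfg)
        assert sd.jitter_report_times(tl) is tl

    def test_constant_latency_shifts_interior_boundaries(self):
        cfg = sd.GammaDwellConfig(5.29, 4.26, min_duration=4.0, seed=8)
        tl = sd.simulate_percept_timeline(420.0, cfg)
        out = sd.jitter_report_times(tl, latency_mean=1.0,
                                     rng=np.random.default_rng(0))
        assert out.total_duration == tl.total_duration
        for a, b in zip(tl.intervals[1:], out.intervals[1:]):
            assert b.onset == pytest.approx(a.onset + 1.0)

    def test_jittered_timeline_remains_valid(self):
        cfg = sd.GammaDwellConfig(2.0, 7.51, min_duration=5.0, seed=9)
        tl = sd.simulate_percept_timeline(420.0, cfg)
        out = sd.jitter_report_times(tl, latency_mean=0.5, latency_sd=0.8,
                                     rng=np.random.default_rng(1))
        states = out.states()
        assert all(a != b for a, b in zip(states, states[1:]))
        assert out.durations().sum() == pytest.approx(420.0)


class TestHrf:
    def test_causal_and_finite_support(self):
        assert sd.canonical_hrf(0.0) == pytest.approx(0.0, abs=1e-6)
        t = np.linspace(30, 40, 50)
        assert np.all(np.abs(sd.canonical_hrf(t)) < 0.01)

    def test_peak_near_five_seconds(self):
        t = np.arange(0, 32, 0.01)
        h = sd.canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.25)

    def test_positive_integral(self):
        t = np.arange(0, 32, 0.01)
        assert np.trapezoid(sd.canonical_hrf(t), t) > 0

    def test_sustained_response_plateaus_at_one(self):
        # normalization contract used by the simulator and design matrices
        ind = np.ones(2000)
        resp = sd.hrf_convolve_indicator(ind, 0.1)
        assert resp[-1] == pytest.approx(1.0, abs=1e-3)


class TestSimulateRun:
    def _timeline(self):
        return sd.simulate_percept_timeline(
            420.0, sd.GammaDwellConfig(5.29, 4.26, min_duration=4.0, seed=5))

    def test_noise_free_run_is_exact_boxcar_convolution(self):
        tl = self._timeline()
        vox = sd.VoxelSpec(grid_shape=(2, 2, 1),
                           object_positive_voxels=[0],
                           object_negative_voxels=[],
                           vessel_voxels=[], positive_effect=1.5)
        noise = sd.NoiseConfig(sigma=0.0, drift_amplitude=0.0)
        run = sd.simulate_run(tl, vox, noise, tr=2.0)
        expected = 100.0 + 1.5 * sd.bold_response(tl, 2.0, run.n_volumes)
        np.testing.assert_allclose(run.as_matrix()[:, 0], expected)
        np.testing.assert_allclose(run.as_matrix()[:, 1], 100.0)

    def test_same_seed_reproduces_run(self):
        tl = self._timeline()
        vox = sd.default_voxel_spec(grid_shape=(4, 4, 2), n_positive=3,
                                    n_negative=3, n_vessel=1,
                                    rng=np.random.default_rng(0))
        noise = sd.NoiseConfig(sigma=0.5, seed=12)
        a = sd.simulate_run(tl, vox, noise, tr=2.0)
        b = sd.simulate_run(tl, vox, noise, tr=2.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empty_grid_rejected(self):
        tl = self._timeline()
        vox = sd.VoxelSpec(grid_shape=(0, 0, 0), object_positive_voxels=[],
                           object_negative_voxels=[], vessel_voxels=[])
        with pytest.raises(InvalidArgumentError):
            sd.simulate_run(tl, vox, sd.NoiseConfig(), tr=2.0)

    def test_disjointness_enforced(self):
        with pytest.raises(InvalidArgumentError):
            sd.VoxelSpec(grid_shape=(2, 2, 2), object_positive_voxels=[0, 1],
                         object_negative_voxels=[1], vessel_voxels=[])


class TestSessionIO:
    def test_round_trip_preserves_shape_tr_and_timeline(self, tmp_path):
        ses = sd.simulate_session(2, sd.ONLINE_PRESET,
                                  voxels=sd.default_voxel_spec(
                                      grid_shape=(4, 4, 2), n_positive=2,
                                      n_negative=2, n_vessel=1,
                                      rng=np.random.default_rng(1)),
                                  seed=3)
        sd.write_session(ses, tmp_path)
        back = sd.read_session(tmp_path)
        assert back.n_runs == ses.n_runs
        assert back.tr == pytest.approx(ses.tr)
        assert back.grid_shape == ses.grid_shape
        for a, b in zip(ses.runs, back.runs):
            assert a.data.shape == b.data.shape
            np.testing.assert_allclose(a.data, b.data, rtol=1e-6)
            assert len(a.timeline.intervals) == len(b.timeline.intervals)

    def test_events_rows_equal_intervals(self, tmp_path):
        import pandas as pd

        ses = sd.simulate_session(1, sd.OFFLINE_PRESET,
                                  voxels=sd.default_voxel_spec(
                                      grid_shape=(3, 3, 2), n_positive=1,
                                      n_negative=1, n_vessel=0,
                                      rng=np.random.default_rng(2)),
                                  seed=4)
        sd.write_session(ses, tmp_path)
        events = pd.read_csv(tmp_path / "run-00_events.tsv", sep="\t")
        assert len(events) == len(ses.runs[0].timeline.intervals)
        assert list(events.columns) == ["onset", "duration", "state"]

    def test_sidecar_seed_regenerates_identical_session(self, tmp_path):
        import json

        ses = sd.simulate_session(2, sd.ONLINE_PRESET,
                                  voxels=sd.default_voxel_spec(
                                      grid_shape=(3, 3, 2), n_positive=1,
                                      n_negative=1, n_vessel=0,
                                      rng=np.random.default_rng(5)),
                                  seed=17)
        sd.write_session(ses, tmp_path)
        with open(tmp_path / "session.json") as fh:
            meta = json.load(fh)
        again = sd.simulate_session(2, sd.PRESETS[meta["preset"]],
                                    voxels=sd.default_voxel_spec(
                                        grid_shape=(3, 3, 2), n_positive=1,
                                        n_negative=1, n_vessel=0,
                                        rng=np.random.default_rng(5)),
                                    seed=meta["seed"])
        for a, b in zip(ses.runs, again.runs):
            np.testing.assert_array_equal(a.data, b.data)
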