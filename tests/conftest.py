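"""Shared fixtures: synthetic sessions and cached pipeline results.

Session-scoped so the expensive objects (simulated sessions, cross-validated
decodings, permutation nulls) are computed once per test run.  Problem
sizes are desk scale: small voxel grids with a planted antagonistic
network, full-length 420 s runs.
"""

import numpy as np
import pytest

from percepttrack import decoding, online_decoder, synthetic_data as sd
from percepttrack import group_transfer as gt


HIGH_SNR_GRID = (12, 12, 6)


@pytest.fixture(scope="session")
def high_snr_voxels():
    rng = np.random.default_rng(7)
    return sd.default_voxel_spec(grid_shape=HIGH_SNR_GRID, n_positive=60,
                                 n_negative=60, n_vessel=10, rng=rng)


@pytest.fixture(scope="session")
def high_snr_session(high_snr_voxels):
    """8-run online-preset session, effect 1.5% / noise sigma 0.3%."""
    return sd.simulate_session(8, sd.ONLINE_PRESET, voxels=high_snr_voxels,
                               noise=sd.NoiseConfig(sigma=0.3), seed=7)


@pytest.fixture(scope="session")
def high_snr_cfg():
    return decoding.CvConfig(k_select=300)


@pytest.fixture(scope="session")
def loro_result(high_snr_session, high_snr_cfg):
    return decoding.loro_cv(high_snr_session, high_snr_cfg)


@pytest.fixture(scope="session")
def online_result(high_snr_session):
    cfg = online_decoder.OnlineConfig(k_initial=300)
    return online_decoder.run_session(high_snr_session, cfg)


@pytest.fixture(scope="session")
def null_session():
    """Zero-effect session: no percept information anywhere."""
    rng = np.random.default_rng(11)
    voxels = sd.default_voxel_spec(grid_shape=(8, 8, 4), n_positive=20,
                                   n_negative=20, n_vessel=5,
                                   positive_effect=0.0, negative_effect=0.0,
                                   rng=rng)
    return sd.simulate_session(4, sd.ONLINE_PRESET, voxels=voxels,
                               noise=sd.NoiseConfig(sigma=0.3), seed=11)


@pytest.fixture(scope="session")
def null_cfg():
    return decoding.CvConfig(k_select=100, lowpass_candidates=(1 / 16,))


@pytest.fixture(scope="session")
def group_cfg():
    return gt.GroupConfig(k_subject=150, k_group=150)


@pytest.fixture(scope="session")
def shared_voxels():
    rng = np.random.default_rng(21)
    return sd.default_voxel_spec(grid_shape=(10, 10, 5), n_positive=50,
                                 n_negative=50, n_vessel=8, rng=rng)


@pytest.fixture(scope="session")
def shared_subjects(shared_voxels, group_cfg):
    """Six subjects sharing one informative map, independent noise."""
    subs = []
    for i in range(6):
        ses = sd.simulate_session(4, sd.ONLINE_PRESET, voxels=shared_voxels,
                                  noise=sd.NoiseConfig(sigma=0.3, seed=100 + i),
                                  seed=100 + i)
        subs.append(gt.prepare_subject(ses, group_cfg, subject_id=i))
    return subs


@pytest.fixture(scope="session")
def disjoint_subjects(group_cfg):
    """Six subjects with disjoint informative maps (negative control)."""
    subs = []
    for i in range(6):
        vox = sd.default_voxel_spec(grid_shape=(10, 10, 5), n_positive=20,
                                    n_negative=20, n_vessel=0,
                                    rng=np.random.default_rng(500 + i))
        ses = sd.simulate_session(4, sd.ONLINE_PRESET, voxels=vox,
                                  noise=sd.NoiseConfig(sigma=0.3, seed=300 + i),
                                  seed=300 + i)
        subs.append(gt.prepare_subject(ses, group_cfg, subject_id=i))
    return subs
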