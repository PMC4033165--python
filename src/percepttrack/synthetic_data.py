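"""Synthetic bistable-percept BOLD sessions with known ground truth.

The generator emulates the study conditions of a slit-viewing bistable
perception experiment: 420 s runs at TR 2.5 s ("offline" preset) or 2.0 s
("online" preset); two-state percept timelines whose dwell times follow a
gamma distribution (offline shape 2.00 / scale 7.51 s, online shape 5.29 /
scale 4.26 s); an antagonistic voxel population in which one subset
responds with higher BOLD signal during object percepts and another with
lower; hemodynamic convolution with a double-gamma impulse response peaking
near 5 s; low-frequency drift plus AR(1) noise; and a minority of "vessel"
voxels oscillating above 10% signal change so the artifact-exclusion rule
has something to catch.

Baseline intensity defaults to 100 signal units so that percent signal
change equals absolute deviation, which keeps effect sizes and the 10%
exclusion threshold directly interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .core import (LINE, OBJECT, Interval, PerceptTimeline, Run, Session,
                   other_state)
from .errors import InvalidArgumentError

HRF_SUPPORT_S = 32.0  # impulse response treated as zero beyond this lag
_HRF_DT = 0.1         # fine time grid (s) for boxcar convolution


@dataclass(frozen=True)
class GammaDwellConfig:
    """Gamma dwell-time distribution for percept intervals.

    shape, scale parameterize the gamma density; draws below
    ``min_duration`` are rejected and redrawn (``min_duration = 0``
    reproduces the untruncated distribution).
    """

    shape: float
    scale: float
    min_duration: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise InvalidArgumentError("gamma shape and scale must be > 0")
        if self.min_duration < 0:
            raise InvalidArgumentError("min_duration must be >= 0")


@dataclass(frozen=True)
class SessionPreset:
    """Acquisition + behavior parameters for one experiment style."""

    name: str
    tr: float
    run_duration: float
    dwell_shape: float
    dwell_scale: float

    def dwell(self, seed: int = 0) -> GammaDwellConfig:
        # minimum dwell of 2 TR keeps every interval visible after the
        # hemodynamic label shift
        return GammaDwellConfig(self.dwell_shape, self.dwell_scale,
                                min_duration=2 * self.tr, seed=seed)


OFFLINE_PRESET = SessionPreset("offline", tr=2.5, run_duration=420.0,
                               dwell_shape=2.00, dwell_scale=7.51)
ONLINE_PRESET = SessionPreset("online", tr=2.0, run_duration=420.0,
                              dwell_shape=5.29, dwell_scale=4.26)
PRESETS = {p.name: p for p in (OFFLINE_PRESET, ONLINE_PRESET)}


@dataclass
class VoxelSpec:
    """Placement and effect sizes of the informative / artifact voxels.

    Index sets are flat C-order indices into the voxel grid and must be
    disjoint.  Effect sizes and vessel amplitude are in percent signal
    change; with the default baseline of 100 they are also absolute units.
    """

    grid_shape: tuple[int, int, int]
    object_positive_voxels: np.ndarray
    object_negative_voxels: np.ndarray
    vessel_voxels: np.ndarray
    positive_effect: float = 1.5
    negative_effect: float = 1.5
    vessel_amplitude: float = 12.0
    vessel_period: float = 20.0
    baseline: float = 100.0

    def __post_init__(self):
        self.object_positive_voxels = np.asarray(self.object_positive_voxels, dtype=int)
        self.object_negative_voxels = np.asarray(self.object_negative_voxels, dtype=int)
        self.vessel_voxels = np.asarray(self.vessel_voxels, dtype=int)
        sets = [set(self.object_positive_voxels), set(self.object_negative_voxels),
                set(self.vessel_voxels)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise InvalidArgumentError("voxel index sets must be disjoint")
        if not np.isfinite([self.positive_effect, self.negative_effect,
                            self.vessel_amplitude]).all():
            raise InvalidArgumentError("effect sizes must be finite")

    @property
    def n_voxels(self) -> int:
        x, y, z = self.grid_shape
        return x * y * z


@dataclass(frozen=True)
class NoiseConfig:
    """Temporal noise model: AR(1) noise with stationary s.d. ``sigma``
    (percent signal change) plus a sinusoidal low-frequency drift."""

    sigma: float = 0.3
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 1.0
    drift_period: float = 300.0  # scanner drift lives below the 1/128 Hz
                                 # high-pass band, hence that standard cutoff
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidArgumentError("sigma must be >= 0")
        if not (0 <= self.ar1_coefficient < 1):
            raise InvalidArgumentError("ar1_coefficient must lie in [0, 1)")


def sample_dwell_times(n: int, dwell: GammaDwellConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n i.i.d. gamma dwell times, rejecting draws below min_duration."""
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    rng = np.random.default_rng(dwell.seed) if rng is None else rng
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(dwell.shape, dwell.scale, size=n - filled)
        keep = draw[draw >= dwell.min_duration]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def simulate_percept_timeline(total_duration: float,
                              dwell: GammaDwellConfig,
                              rng: np.random.Generator | None = None) -> PerceptTimeline:
    """Alternating two-state timeline with gamma dwell times.

    The initial state is a fair coin flip from the configured seed; the last
    interval is truncated at ``total_duration``.
    """
    if total_duration <= 0:
        raise InvalidArgumentError("total_duration must be positive")
    rng = np.random.default_rng(dwell.seed) if rng is None else rng
    state = LINE if rng.random() < 0.5 else OBJECT
    intervals = []
    t = 0.0
    while t < total_duration:
        d = float(sample_dwell_times(1, dwell, rng)[0])
        d = min(d, total_duration - t)
        intervals.append(Interval(t, d, state))
        t += d
        state = other_state(state)
    return PerceptTimeline(tuple(intervals), total_duration)


def jitter_report_times(timeline: PerceptTimeline, latency_mean: float = 0.0,
                        latency_sd: float = 0.0,
                        rng: np.random.Generator | None = None
                        ) -> PerceptTimeline:
    """Emulate button-press report latency: each interval boundary is
    delayed by latency_mean + N(0, latency_sd), clipped so intervals stay
    positive and ordered.  Defaults leave the timeline unchanged."""
    if latency_mean == 0.0 and latency_sd == 0.0:
        return timeline
    rng = np.random.default_rng(0) if rng is None else rng
    bounds = np.array([iv.onset for iv in timeline.intervals[1:]])
    shifted = bounds + latency_mean + rng.normal(0.0, latency_sd, bounds.size)
    shifted = np.clip(shifted, 1e-3, timeline.total_duration - 1e-3)
    shifted = np.maximum.accumulate(shifted)  # keep boundaries ordered
    # drop boundaries pushed onto each other (interval swallowed by latency)
    onsets = [0.0]
    states = [timeline.intervals[0].state]
    for b, iv in zip(shifted, timeline.intervals[1:]):
        if b - onsets[-1] <= 1e-3:
            continue
        if iv.state == states[-1]:
            continue
        onsets.append(float(b))
        states.append(iv.state)
    intervals = []
    for i, (on, st) in enumerate(zip(onsets, states)):
        end = onsets[i + 1] if i + 1 < len(onsets) else timeline.total_duration
        intervals.append(Interval(on, end - on, st))
    return PerceptTimeline(tuple(intervals), timeline.total_duration)


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response.

    Positive lobe gamma(6, 1) (mode 5 s), undershoot gamma(16, 1)/6
    (trough near 15 s), zero outside [0, 32] s, peak-normalized to 1.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    h = np.where((t < 0) | (t > HRF_SUPPORT_S), 0.0, h)
    peak = stats.gamma.pdf(5.0, 6.0) - stats.gamma.pdf(5.0, 16.0) / 6.0
    return h / peak


def hrf_convolve_indicator(indicator: np.ndarray, dt: float) -> np.ndarray:
    """Convolve a fine-grid state indicator with the canonical HRF.

    Normalized so a sustained state converges to a plateau of exactly 1,
    which makes planted effect sizes equal to the steady-state percent
    signal change.
    """
    kernel = canonical_hrf(np.arange(0, HRF_SUPPORT_S + dt, dt))
    kernel = kernel / (kernel.sum() * dt)
    return np.convolve(indicator, kernel)[: indicator.size] * dt


def state_indicator(timeline: PerceptTimeline, state: str, dt: float,
                    n_samples: int) -> np.ndarray:
    """Fine-grid 0/1 indicator of the given state at times k*dt."""
    ind = np.zeros(n_samples)
    for iv in timeline.intervals:
        if iv.state != state:
            continue
        a = int(np.ceil(iv.onset / dt - 1e-9))
        b = int(np.ceil(iv.end / dt - 1e-9))
        ind[a:min(b, n_samples)] = 1.0
    return ind


def bold_response(timeline: PerceptTimeline, tr: float, n_volumes: int,
                  state: str = OBJECT, dt: float = _HRF_DT) -> np.ndarray:
    """Expected normalized BOLD time course for one state, sampled at k*TR."""
    n_fine = int(np.ceil(n_volumes * tr / dt))
    ind = state_indicator(timeline, state, dt, n_fine)
    resp = hrf_convolve_indicator(ind, dt)
    idx = np.clip(np.round(np.arange(n_volumes) * tr / dt).astype(int), 0, n_fine - 1)
    return resp[idx]


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               sigma: float, phi: float) -> np.ndarray:
    """AR(1) noise (T, V) with stationary standard deviation sigma."""
    n_t, n_v = shape
    if sigma == 0:
        return np.zeros(shape)
    e = np.empty(shape)
    innov_sd = sigma * np.sqrt(1.0 - phi ** 2)
    e[0] = rng.normal(0.0, sigma, n_v)
    z = rng.normal(0.0, innov_sd, (n_t - 1, n_v))
    for t in range(1, n_t):
        e[t] = phi * e[t - 1] + z[t - 1]
    return e


def simulate_run(timeline: PerceptTimeline, voxels: VoxelSpec,
                 noise: NoiseConfig, tr: float, run_index: int = 0,
                 rng: np.random.Generator | None = None) -> Run:
    """Simulate one run on the voxel grid.

    Each voxel's series is baseline + effect * (OBJECT boxcar convolved with
    the HRF) + drift + AR(1) noise; object-negative voxels enter with a
    negative effect, vessel voxels get a sinusoid of the configured
    amplitude instead of a percept response.
    """
    if tr <= 0:
        raise InvalidArgumentError("tr must be positive")
    if voxels.n_voxels == 0:
        raise InvalidArgumentError("voxel grid must be non-empty")
    rng = np.random.default_rng(noise.seed) if rng is None else rng
    n_vol = int(np.floor(timeline.total_duration / tr + 1e-9))
    n_v = voxels.n_voxels
    t_vol = np.arange(n_vol) * tr

    series = np.full((n_vol, n_v), float(voxels.baseline))
    resp = bold_response(timeline, tr, n_vol, state=OBJECT)
    pct = voxels.baseline / 100.0  # percent -> signal units
    if voxels.object_positive_voxels.size:
        series[:, voxels.object_positive_voxels] += \
            voxels.positive_effect * pct * resp[:, None]
    if voxels.object_negative_voxels.size:
        series[:, voxels.object_negative_voxels] -= \
            voxels.negative_effect * pct * resp[:, None]
    if voxels.vessel_voxels.size:
        phase = rng.uniform(0, 2 * np.pi, voxels.vessel_voxels.size)
        osc = np.sin(2 * np.pi * t_vol[:, None] / voxels.vessel_period + phase)
        series[:, voxels.vessel_voxels] += voxels.vessel_amplitude * pct * osc

    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, n_v)
        series += noise.drift_amplitude * pct * \
            np.sin(2 * np.pi * t_vol[:, None] / noise.drift_period + phase)
    series += _ar1_noise(rng, (n_vol, n_v), noise.sigma * pct,
                         noise.ar1_coefficient)

    data = series.T.reshape(*voxels.grid_shape, n_vol)
    return Run(data=data, tr=tr, run_index=run_index, timeline=timeline)


def default_voxel_spec(grid_shape=(20, 20, 10), n_positive=100, n_negative=100,
                       n_vessel=20, positive_effect=1.5, negative_effect=1.5,
                       vessel_amplitude=12.0, baseline=100.0,
                       rng: np.random.Generator | None = None) -> VoxelSpec:
    """Randomly place disjoint informative and vessel voxel sets."""
    rng = np.random.default_rng(0) if rng is None else rng
    n_total = int(np.prod(grid_shape))
    need = n_positive + n_negative + n_vessel
    if need > n_total:
        raise InvalidArgumentError("more special voxels requested than grid size")
    chosen = rng.choice(n_total, size=need, replace=False)
    return VoxelSpec(
        grid_shape=tuple(grid_shape),
        object_positive_voxels=chosen[:n_positive],
        object_negative_voxels=chosen[n_positive:n_positive + n_negative],
        vessel_voxels=chosen[n_positive + n_negative:],
        positive_effect=positive_effect,
        negative_effect=negative_effect,
        vessel_amplitude=vessel_amplitude,
        baseline=baseline,
    )


def simulate_session(n_runs: int, preset: SessionPreset = ONLINE_PRESET,
                     voxels: VoxelSpec | None = None,
                     noise: NoiseConfig | None = None,
                     seed: int = 0) -> Session:
    """Simulate a full session: independent timelines and noise per run,
    one shared voxel specification (the subject's functional anatomy)."""
    if n_runs < 1:
        raise InvalidArgumentError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    if voxels is None:
        voxels = default_voxel_spec(rng=rng)
    if noise is None:
        noise = NoiseConfig()
    dwell = preset.dwell()
    runs = []
    for i in range(n_runs):
        timeline = simulate_percept_timeline(preset.run_duration, dwell, rng)
        runs.append(simulate_run(timeline, voxels, noise, preset.tr,
                                 run_index=i, rng=rng))
    return Session(runs, meta={"preset": preset.name, "seed": seed})


# ---------------------------------------------------------------------------
# on-disk format: NIfTI-1 volumes + BIDS-like events TSV + JSON sidecar

def write_session(session: Session, directory) -> list[Path]:
    """Write one NIfTI file + events TSV per run, plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in session.runs:
        stem = f"run-{run.run_index:02d}"
        img = nib.Nifti1Image(run.data.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
        nii = directory / f"{stem}_bold.nii.gz"
        img.to_filename(str(nii))
        events = pd.DataFrame({
            "onset": [iv.onset for iv in run.timeline.intervals],
            "duration": [iv.duration for iv in run.timeline.intervals],
            "state": [iv.state for iv in run.timeline.intervals],
        })
        tsv = directory / f"{stem}_events.tsv"
        events.to_csv(tsv, sep="\t", index=False)
        paths.extend([nii, tsv])
    sidecar = directory / "session.json"
    with open(sidecar, "w") as fh:
        json.dump({"tr_s": session.tr, "n_runs": session.n_runs,
                   **session.meta}, fh, indent=1)
    paths.append(sidecar)
    return paths


def read_session(directory) -> Session:
    """Read a session previously written by :func:`write_session`."""
    directory = Path(directory)
    sidecar = directory / "session.json"
    try:
        with open(sidecar) as fh:
            meta = json.load(fh)
    except OSError as exc:
        raise InvalidArgumentError(f"cannot read sidecar {sidecar}: {exc}") from exc
    tr = float(meta["tr_s"])
    runs = []
    for nii in sorted(directory.glob("run-*_bold.nii.gz")):
        stem = nii.name.replace("_bold.nii.gz", "")
        idx = int(stem.split("-")[1])
        img = nib.load(str(nii))
        data = np.asarray(img.dataobj, dtype=np.float32)
        events = pd.read_csv(directory / f"{stem}_events.tsv", sep="\t")
        intervals = tuple(Interval(float(r.onset), float(r.duration), str(r.state))
                          for r in events.itertuples())
        total = intervals[-1].onset + intervals[-1].duration
        timeline = PerceptTimeline(intervals, total)
        runs.append(Run(data=data, tr=tr, run_index=idx, timeline=timeline))
    if not runs:
        raise InvalidArgumentError(f"no runs found under {directory}")
    meta.pop("tr_s", None)
    meta.pop("n_runs", None)
    return Session(runs, meta=meta)
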