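"""Raw run series -> filtered, centered, artifact-screened features + labels.

All temporal operations work on (T, V) matrices: rows are volumes, columns
voxels.  Band-pass filtering uses a Butterworth design in second-order
sections; the offline path applies it forward-backward (zero phase), the
online path forward only, because a real-time loop cannot see the future.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import LABEL_OF_STATE, LABEL_UNDEFINED, PerceptTimeline
from .errors import InvalidArgumentError, MissingBaselineError

ZERO_PHASE = "zero_phase"
CAUSAL = "causal"


@dataclass(frozen=True)
class FilterConfig:
    """Butterworth band-pass: passband (highpass_cut, lowpass_cut) Hz."""

    highpass_cut: float
    lowpass_cut: float
    order: int = 4
    mode: str = ZERO_PHASE

    def __post_init__(self):
        if not (0 < self.highpass_cut < self.lowpass_cut):
            raise InvalidArgumentError("need 0 < highpass_cut < lowpass_cut")
        if self.order < 1:
            raise InvalidArgumentError("filter order must be >= 1")
        if self.mode not in (ZERO_PHASE, CAUSAL):
            raise InvalidArgumentError(f"unknown filter mode {self.mode!r}")


def zero_center(series: np.ndarray,
                baseline: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Remove the per-voxel baseline, returning (centered, baseline).

    Offline: baseline is the series' own temporal mean.  Online: pass the
    stored training-run baseline so new volumes are centered without
    recomputation.
    """
    series = np.asarray(series, dtype=float)
    if baseline is None:
        baseline = series.mean(axis=0)
    else:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != series.shape[-1:]:
            raise MissingBaselineError(
                f"stored baseline has shape {baseline.shape}, "
                f"expected ({series.shape[-1]},)")
    return series - baseline, baseline


def butter_sos(tr: float, cfg: FilterConfig) -> np.ndarray:
    """Second-order-section coefficients for the band-pass at sampling 1/TR.

    Coefficient convention: ``scipy.signal.butter(..., output='sos')`` with
    critical frequencies in Hz and ``fs = 1/tr``; tests validate the
    transfer function against an FFT amplitude oracle rather than
    coefficient values.
    """
    nyquist = 0.5 / tr
    if cfg.lowpass_cut >= nyquist:
        raise InvalidArgumentError(
            f"lowpass_cut {cfg.lowpass_cut:.4f} Hz >= Nyquist {nyquist:.4f} Hz")
    return signal.butter(cfg.order, [cfg.highpass_cut, cfg.lowpass_cut],
                         btype="bandpass", fs=1.0 / tr, output="sos")


def bandpass(series: np.ndarray, tr: float, cfg: FilterConfig) -> np.ndarray:
    """Band-pass filter each column of (T, V); zero-phase or causal."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] <= 3 * cfg.order:
        raise InvalidArgumentError("series too short for the filter order")
    sos = butter_sos(tr, cfg)
    if cfg.mode == ZERO_PHASE:
        return signal.sosfiltfilt(sos, series, axis=0)
    return signal.sosfilt(sos, series, axis=0)


def highpass_sos(tr: float, cut_hz: float, order: int = 1) -> np.ndarray:
    """Second-order sections for a causal Butterworth high-pass."""
    nyquist = 0.5 / tr
    if not (0 < cut_hz < nyquist):
        raise InvalidArgumentError("high-pass cut must lie in (0, Nyquist)")
    return signal.butter(order, cut_hz, btype="highpass", fs=1.0 / tr,
                         output="sos")


class CausalFilter:
    """Streaming causal filter: one volume in, one filtered volume out.

    Filter state starts at rest (zero), matching a baseline-centered signal
    that begins near zero; feeding a run volume-by-volume reproduces
    ``scipy.signal.sosfilt`` on the whole run exactly.
    """

    def __init__(self, sos: np.ndarray, n_voxels: int):
        self.sos = np.asarray(sos)
        self.n_voxels = n_voxels
        self.reset()

    def reset(self) -> None:
        self.zi = np.zeros((self.sos.shape[0], 2, self.n_voxels))

    def step(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_voxels,):
            raise InvalidArgumentError(
                f"expected volume of {self.n_voxels} voxels, got {x.shape}")
        y, self.zi = signal.sosfilt(self.sos, x[None, :], axis=0, zi=self.zi)
        return y[0]


class CausalBandpass(CausalFilter):
    """Streaming causal band-pass built from a :class:`FilterConfig`."""

    def __init__(self, tr: float, cfg: FilterConfig, n_voxels: int):
        if cfg.mode != CAUSAL:
            raise InvalidArgumentError("CausalBandpass requires causal mode")
        super().__init__(butter_sos(tr, cfg), n_voxels)


def exclude_high_signal_change_voxels(series: np.ndarray,
                                      threshold: float = 0.10,
                                      baseline: np.ndarray | None = None
                                      ) -> tuple[np.ndarray, dict]:
    """Screen out voxels exceeding the signal-change threshold.

    A voxel is excluded iff max_t |s(t) - baseline| / baseline > threshold
    (strict), with baseline the per-voxel temporal mean unless supplied.
    Voxels with non-positive baseline are excluded with a warning.  Returns
    (retained flat indices, report dict).  Applying the rule to already
    retained voxels is idempotent.
    """
    series = np.asarray(series, dtype=float)
    if baseline is None:
        baseline = series.mean(axis=0)
    nonpos = baseline <= 0
    if nonpos.any():
        warnings.warn(f"{int(nonpos.sum())} voxels have non-positive baseline; excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(series - baseline).max(axis=0) / baseline
    excluded = nonpos | (rel > threshold)
    retained = np.flatnonzero(~excluded)
    report = {
        "n_total": series.shape[1],
        "n_excluded": int(excluded.sum()),
        "excluded_indices": np.flatnonzero(excluded),
        "threshold": threshold,
    }
    return retained, report


def labels_per_volume(timeline: PerceptTimeline, tr: float, n_volumes: int,
                      hrf_delay: float = 5.0) -> np.ndarray:
    """Per-volume percept labels, shifted by the hemodynamic delay.

    Volume k (acquired over [kT, (k+1)T)) is labeled with the state
    occupying the majority of the shifted window [kT - d, (k+1)T - d).
    Windows that begin before the run start get label 0 (undefined) and are
    excluded from training and accuracy denominators.  A tied majority is
    resolved to the state occupying the earlier part of the window.
    """
    if tr <= 0:
        raise InvalidArgumentError("tr must be positive")
    labels = np.zeros(n_volumes, dtype=int)
    for k in range(n_volumes):
        a = k * tr - hrf_delay
        b = (k + 1) * tr - hrf_delay
        if a < -1e-9:
            labels[k] = LABEL_UNDEFINED
            continue
        overlap = {}
        for iv in timeline.intervals:
            lo, hi = max(a, iv.onset), min(b, iv.end)
            if hi > lo:
                overlap[iv.state] = overlap.get(iv.state, 0.0) + (hi - lo)
        if not overlap:  # window beyond timeline end: last state persists
            labels[k] = LABEL_OF_STATE[timeline.intervals[-1].state]
            continue
        best = max(overlap.values())
        winners = [s for s, v in overlap.items() if abs(v - best) <= 1e-9]
        if len(winners) == 1:
            labels[k] = LABEL_OF_STATE[winners[0]]
        else:
            labels[k] = LABEL_OF_STATE[timeline.state_at(a)]
    return labels


def smooth_spatial(volume: np.ndarray, fwhm_mm: float,
                   voxel_size_mm: float = 3.0) -> np.ndarray:
    """Isotropic Gaussian smoothing of a 3D volume (or 4D series, smoothing
    each volume); sigma = FWHM / (2 sqrt(2 ln 2)), nearest-edge handling."""
    if fwhm_mm < 0:
        raise InvalidArgumentError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    volume = np.asarray(volume, dtype=float)
    if volume.ndim == 4:
        sigma = (sigma_vox, sigma_vox, sigma_vox, 0.0)
    elif volume.ndim == 3:
        sigma = sigma_vox
    else:
        raise InvalidArgumentError("expected a 3D volume or 4D series")
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="nearest")
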