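"""Simulated asynchronous real-time decoding loop.

Protocol: the first two runs are used for vessel exclusion, baseline
estimation, temporal filtering, univariate selection of the 10,000 smallest
p-values, first-pass classifier training, multivariate refinement (keep
|w| > 0.1 max |w|), and retraining on the refined set.  From the third run
onward each incoming volume is baseline-subtracted, advanced one sample
through the causal temporal filter, and classified; a switch event is
emitted whenever the predicted percept changes.  After every completed run
(from the third on) the classifier is retrained on all completed runs; the
feature set stays fixed after the initial selection.

Everything here is causal: the prediction for volume t depends only on
volumes <= t of the current run plus previously completed runs.

The causal temporal filter defaults to a first-order high-pass at
1/128 Hz (drift removal) with NO low-pass.  Any causal low-pass in the
0.06 Hz range carries several seconds of group delay right in the percept
band, which would lag every decoded switch by two to eight volumes and cap
tracking accuracy far below what the signal supports; the noise averaging
a temporal low-pass provides offline is supplied here by spatial pooling
across the multivariate weight map instead.  Setting ``lowpass_hz``
restores a causal band-pass for comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoding, preprocessing as pp
from . import feature_selection as fs
from .core import LinearModel, PerceptTimeline, Run, Session
from .errors import InvalidArgumentError, InvalidSessionError

DEFAULT_PROCESSING_DELAY_S = 2.3  # data transfer + classification latency
                                  # (configurable metadata, never measured)


@dataclass(frozen=True)
class OnlineConfig:
    """``lowpass_hz = None`` (default) streams through a causal high-pass
    only; a float restores a causal band-pass (see module docstring).

    Feature *selection* on the two completed training runs is a different
    matter: those runs are fully acquired, so the univariate pass and the
    multivariate refinement see them through the offline-style zero-phase
    band-pass (1/128-1/16 Hz, fourth order), which stabilizes voxel ranking
    and refinement weights.  Only the classifier that actually runs in the
    loop is trained on causally filtered features.
    """

    highpass_hz: float = 1 / 128
    lowpass_hz: float | None = None
    filter_order: int = 1
    selection_lowpass_hz: float = 1 / 16
    selection_filter_order: int = 2  # scipy N: band-pass of overall order 4
    hrf_delay_s: float = 5.0
    k_initial: int = 10000
    refine_factor: float = 0.1
    C: float = 1.0
    signal_change_threshold: float = 0.10
    processing_delay_s: float = DEFAULT_PROCESSING_DELAY_S

    def sos(self, tr: float) -> np.ndarray:
        if self.lowpass_hz is None:
            return pp.highpass_sos(tr, self.highpass_hz, self.filter_order)
        fc = pp.FilterConfig(self.highpass_hz, self.lowpass_hz,
                             self.filter_order, pp.CAUSAL)
        return pp.butter_sos(tr, fc)


@dataclass(frozen=True)
class SwitchEvent:
    """Emitted the moment the decoded percept changes state."""

    run_index: int
    volume_index: int
    new_label: int
    decision_value: float


@dataclass
class OnlineState:
    model: LinearModel
    baseline: np.ndarray          # per retained voxel, from runs 1-2
    retained: np.ndarray          # flat grid indices surviving exclusion
    feature_cols: np.ndarray      # columns of `retained` used by the model
    filter: pp.CausalFilter       # streaming filter over feature columns
    cfg: OnlineConfig
    tr: float
    completed_raw: list[np.ndarray] = field(default_factory=list)
    completed_timelines: list[PerceptTimeline] = field(default_factory=list)
    current_buffer: list[np.ndarray] = field(default_factory=list)
    last_label: int | None = None
    current_run_index: int | None = None

    @property
    def completed_runs(self) -> int:
        return len(self.completed_raw)


@dataclass
class OnlineResult:
    run_index: np.ndarray
    volume_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    decision: np.ndarray
    events: list[SwitchEvent]
    per_run_accuracy: dict[int, float]
    latency_s: float  # TR + configured processing delay (metadata only)

    @property
    def accuracy(self) -> float:
        mask = self.y_true != 0
        return float(np.mean(self.y_pred[mask] == self.y_true[mask]))


def _flatten(run: Run) -> np.ndarray:
    return run.as_matrix()


def _causal_filtered(state: OnlineState, mat: np.ndarray) -> np.ndarray:
    """Whole-run causal filtering from rest, as the stream would produce."""
    from scipy import signal

    return signal.sosfilt(state.cfg.sos(state.tr), mat, axis=0)


def _training_matrices(state: OnlineState) -> tuple[np.ndarray, np.ndarray]:
    """Stacked defined-label feature rows over all completed runs."""
    xs, ys = [], []
    for mat, timeline in zip(state.completed_raw, state.completed_timelines):
        filt = _causal_filtered(state, mat)
        lab = pp.labels_per_volume(timeline, state.tr, mat.shape[0],
                                   state.cfg.hrf_delay_s)
        mask = lab != 0
        xs.append(filt[mask][:, state.feature_cols])
        ys.append(lab[mask])
    return np.vstack(xs), np.concatenate(ys)


def initial_training(run1: Run, run2: Run,
                     cfg: OnlineConfig = OnlineConfig()) -> OnlineState:
    """Feature selection and initial classifier from the first two runs."""
    tr = run1.tr
    mats = [_flatten(run1), _flatten(run2)]

    retained_mask = None
    for mat in mats:
        keep, _ = pp.exclude_high_signal_change_voxels(
            mat, threshold=cfg.signal_change_threshold)
        mask = np.zeros(mat.shape[1], dtype=bool)
        mask[keep] = True
        retained_mask = mask if retained_mask is None else retained_mask & mask
    retained = np.flatnonzero(retained_mask)

    baseline = np.vstack(mats)[:, retained].mean(axis=0)
    centered = [m[:, retained] - baseline for m in mats]

    from scipy import signal

    sos = cfg.sos(tr)
    # completed runs: zero-phase band-pass for selection and refinement
    sel_fc = pp.FilterConfig(cfg.highpass_hz, cfg.selection_lowpass_hz,
                             cfg.selection_filter_order, pp.ZERO_PHASE)
    filtered = [pp.bandpass(c, tr, sel_fc) for c in centered]
    labels = [pp.labels_per_volume(r.timeline, tr, r.n_volumes, cfg.hrf_delay_s)
              for r in (run1, run2)]

    # univariate pass: per-run GLM F averaged over the two runs
    fsum = None
    for filt, lab in zip(filtered, labels):
        design = fs.design_from_labels(lab, tr, cfg.hrf_delay_s)
        f, _ = fs.univariate_scores(filt, design)
        fsum = f if fsum is None else fsum + f
    fmean = fsum / 2.0
    from scipy import stats as st

    p = st.f.sf(fmean, 1, filtered[0].shape[0] - 3)
    first_pass = fs.select_top_k(fmean, p, cfg.k_initial)

    X = np.vstack([filt[lab != 0][:, first_pass]
                   for filt, lab in zip(filtered, labels)])
    y = np.concatenate([lab[lab != 0] for lab in labels])
    model0 = decoding.train(X, y, C=cfg.C)
    refined_local = fs.multivariate_refine(
        model0.w, fs.RefineConfig(cfg.refine_factor))
    feature_cols = first_pass[refined_local]

    state = OnlineState(
        model=LinearModel(np.zeros(feature_cols.size), 0.0,
                          retained[feature_cols], C=cfg.C),
        baseline=baseline, retained=retained, feature_cols=feature_cols,
        filter=pp.CausalFilter(sos, feature_cols.size),
        cfg=cfg, tr=tr,
        completed_raw=centered,
        completed_timelines=[run1.timeline, run2.timeline],
    )
    Xr, yr = _training_matrices(state)
    state.model = decoding.train(Xr, yr, C=cfg.C,
                                 voxel_indices=retained[feature_cols])
    return state


def start_run(state: OnlineState, run_index: int) -> None:
    """Open a new streaming run: reset the causal filter, keep the decoded
    percept memory so switch events stay alternating across runs."""
    state.filter.reset()
    state.current_buffer = []
    state.current_run_index = run_index


def process_volume(state: OnlineState, volume: np.ndarray
                   ) -> tuple[int, float, SwitchEvent | None]:
    """Classify one incoming volume; emit a switch event when the decoded
    percept changes relative to the previous prediction."""
    volume = np.asarray(volume, dtype=float)
    expected = state.retained.max(initial=-1) + 1
    flat = volume.reshape(-1)
    if flat.size < expected:
        raise InvalidArgumentError(
            f"volume has {flat.size} voxels, expected >= {expected}")
    x = flat[state.retained] - state.baseline
    state.current_buffer.append(x)
    filt = state.filter.step(x[state.feature_cols])
    labels, dec = decoding.predict(state.model, filt[None, :])
    label, d = int(labels[0]), float(dec[0])
    event = None
    if state.last_label is not None and label != state.last_label:
        event = SwitchEvent(run_index=state.current_run_index or 0,
                            volume_index=len(state.current_buffer) - 1,
                            new_label=label, decision_value=d)
    state.last_label = label
    return label, d, event


def retrain_after_run(state: OnlineState, timeline: PerceptTimeline) -> None:
    """Close the current run and retrain on all completed runs.

    The feature set stays fixed; labels come from the run's reported
    percepts, shifted by the hemodynamic delay.
    """
    if state.completed_runs < 2:
        raise InvalidSessionError("initial training must complete first")
    state.completed_raw.append(np.vstack(state.current_buffer))
    state.completed_timelines.append(timeline)
    state.current_buffer = []
    Xr, yr = _training_matrices(state)
    state.model = decoding.train(Xr, yr, C=state.cfg.C,
                                 voxel_indices=state.model.voxel_indices)


def run_session(session: Session,
                cfg: OnlineConfig = OnlineConfig()) -> OnlineResult:
    """Full simulated online protocol over a session of >= 3 runs."""
    if session.n_runs < 3:
        raise InvalidSessionError("online protocol needs at least 3 runs")
    state = initial_training(session.runs[0], session.runs[1], cfg)
    recs = {k: [] for k in ("run", "vol", "true", "pred", "dec")}
    events: list[SwitchEvent] = []
    per_run = {}
    for run in session.runs[2:]:
        start_run(state, run.run_index)
        lab = pp.labels_per_volume(run.timeline, session.tr, run.n_volumes,
                                   cfg.hrf_delay_s)
        mat = run.as_matrix()
        preds = np.empty(run.n_volumes, dtype=int)
        decs = np.empty(run.n_volumes)
        for t in range(run.n_volumes):
            label, d, ev = process_volume(state, mat[t])
            preds[t], decs[t] = label, d
            if ev is not None:
                events.append(ev)
        mask = lab != 0
        per_run[run.run_index] = float(np.mean(preds[mask] == lab[mask]))
        recs["run"].append(np.full(run.n_volumes, run.run_index))
        recs["vol"].append(np.arange(run.n_volumes))
        recs["true"].append(lab)
        recs["pred"].append(preds)
        recs["dec"].append(decs)
        retrain_after_run(state, run.timeline)
    return OnlineResult(
        run_index=np.concatenate(recs["run"]),
        volume_index=np.concatenate(recs["vol"]),
        y_true=np.concatenate(recs["true"]),
        y_pred=np.concatenate(recs["pred"]),
        decision=np.concatenate(recs["dec"]),
        events=events, per_run_accuracy=per_run,
        latency_s=session.tr + cfg.processing_delay_s,
    )
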