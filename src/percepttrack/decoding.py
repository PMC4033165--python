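"""Linear max-margin decoding of percepts and leave-one-run-out CV.

The classifier is a soft-margin linear SVM; prediction is
``label = sign(w . x + b)`` with a decision value of exactly 0 mapped to
+1 (OBJECT) by convention.  Features are band-pass-filtered, zero-centered
voxel signal changes; no further standardization is applied.

Cross-validation holds out one run at a time.  Inside each training fold,
the low-pass cutoff is optimized by an inner leave-one-run-out loop over
the training runs, and univariate feature selection sees training-fold
data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import feature_selection as fs
from . import preprocessing as pp
from .core import LinearModel, Session
from .errors import (InvalidArgumentError, InvalidSessionError,
                     InvalidTrainingSetError)


@dataclass(frozen=True)
class CvConfig:
    """Decoding pipeline configuration.

    ``lowpass_candidates`` are the low-pass cutoffs tried in the inner
    optimization (a single-element tuple disables the search).  ``k_select``
    is the number of voxels retained by univariate selection; the SVM
    regularization C defaults to 1.
    """

    lowpass_candidates: tuple[float, ...] = (1 / 27, 1 / 18, 1 / 12, 1 / 8)
    highpass_hz: float = 1 / 128
    filter_order: int = 4
    hrf_delay_s: float = 5.0
    k_select: int = 5000
    C: float = 1.0
    signal_change_threshold: float = 0.10
    smooth_fwhm_mm: float = 0.0
    voxel_size_mm: float = 3.0


@dataclass
class PreparedSession:
    """Label-independent preprocessing shared across folds and permutations.

    ``filtered[cutoff][r]`` is the (T, V_retained) matrix of run r after
    zero-centering and zero-phase band-pass at that low-pass cutoff;
    ``retained`` maps columns back to flat grid indices.
    """

    filtered: dict[float, list[np.ndarray]]
    retained: np.ndarray
    labels: list[np.ndarray]
    tr: float
    grid_shape: tuple[int, int, int]
    cfg: CvConfig

    @property
    def n_runs(self) -> int:
        return len(self.labels)


@dataclass
class DecodingResult:
    """Per-volume predictions from cross-validated decoding."""

    run_index: np.ndarray
    volume_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    decision: np.ndarray
    fold_accuracy: dict[int, float] = field(default_factory=dict)
    chosen_cutoff: dict[int, float] = field(default_factory=dict)
    selected_voxels: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "run": self.run_index, "volume": self.volume_index,
            "decision_value": self.decision,
            "predicted": self.y_pred, "true": self.y_true,
        })


def train(X: np.ndarray, y: np.ndarray, C: float = 1.0,
          voxel_indices: np.ndarray | None = None) -> LinearModel:
    """Fit the soft-margin linear SVM; deterministic given data and C."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise InvalidTrainingSetError("features must be finite")
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidTrainingSetError("training data contains a single class")
    svc = SVC(kernel="linear", C=C, tol=1e-6)
    svc.fit(X, y)
    # sklearn orders classes ascending ([-1, +1]); positive decision values
    # vote for +1, matching the sign convention of predict()
    w = svc.coef_[0].copy()
    b = float(svc.intercept_[0])
    if voxel_indices is None:
        voxel_indices = np.arange(X.shape[1])
    return LinearModel(w=w, b=b, voxel_indices=voxel_indices, C=C)


def predict(model: LinearModel, X: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values for feature rows X; sign(0) -> +1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w.size:
        raise InvalidArgumentError(
            f"feature dimension {X.shape[1]} != model dimension {model.w.size}")
    d = X @ model.w + model.b
    labels = np.where(d >= 0, 1, -1)
    return labels, d


def prepare_session(session: Session, cfg: CvConfig) -> PreparedSession:
    """Run every label-independent preprocessing step once.

    Order mirrors the acquisition pipeline: optional spatial smoothing,
    vessel-artifact exclusion (session-wide, from raw intensities), then
    per-run zero-centering and zero-phase band-pass filtering at each
    candidate low-pass cutoff.
    """
    raws = []
    for run in session.runs:
        data = run.data
        if cfg.smooth_fwhm_mm > 0:
            data = pp.smooth_spatial(data, cfg.smooth_fwhm_mm, cfg.voxel_size_mm)
        raws.append(data.reshape(session.n_voxels, run.n_volumes).T)

    retained_mask = np.ones(session.n_voxels, dtype=bool)
    for mat in raws:
        keep, _ = pp.exclude_high_signal_change_voxels(
            mat, threshold=cfg.signal_change_threshold)
        mask = np.zeros(session.n_voxels, dtype=bool)
        mask[keep] = True
        retained_mask &= mask
    retained = np.flatnonzero(retained_mask)
    raws = [m[:, retained] for m in raws]

    filtered = {}
    for cut in sorted(set(cfg.lowpass_candidates)):
        fc = pp.FilterConfig(cfg.highpass_hz, cut, cfg.filter_order, pp.ZERO_PHASE)
        per_run = []
        for mat in raws:
            centered, _ = pp.zero_center(mat)
            per_run.append(pp.bandpass(centered, session.tr, fc))
        filtered[cut] = per_run

    labels = [pp.labels_per_volume(run.timeline, session.tr, run.n_volumes,
                                   cfg.hrf_delay_s)
              for run in session.runs]
    return PreparedSession(filtered=filtered, retained=retained, labels=labels,
                           tr=session.tr, grid_shape=session.grid_shape, cfg=cfg)


def _stack_defined(prep: PreparedSession, cutoff: float, run_ids,
                   labels_by_run) -> tuple[np.ndarray, np.ndarray]:
    """Defined-label rows of the given runs, stacked."""
    xs, ys = [], []
    for r in run_ids:
        lab = labels_by_run[r]
        mask = lab != 0
        xs.append(prep.filtered[cutoff][r][mask])
        ys.append(lab[mask])
    return np.vstack(xs), np.concatenate(ys)


def _run_scores(prep: PreparedSession, cutoff: float, r: int, labels_by_run,
                cache: dict | None) -> np.ndarray:
    """Per-voxel GLM contrast F for one run at one cutoff (memoized within
    a CV, where labels are fixed)."""
    key = (cutoff, r)
    if cache is not None and key in cache:
        return cache[key]
    design = fs.design_from_labels(labels_by_run[r], prep.tr,
                                   prep.cfg.hrf_delay_s)
    f, _ = fs.univariate_scores(prep.filtered[cutoff][r], design)
    if cache is not None:
        cache[key] = f
    return f


def _select_on_runs(prep: PreparedSession, cutoff: float, run_ids,
                    labels_by_run, k: int, cache: dict | None = None
                    ) -> np.ndarray:
    """Univariate top-k selection from the given training runs only.

    One GLM per training run (design rebuilt from that run's shifted
    labels, so the HRF model never crosses a run boundary); per-voxel F
    statistics are averaged over the training runs and ranked.
    """
    fvals = None
    for r in run_ids:
        f = _run_scores(prep, cutoff, r, labels_by_run, cache)
        fvals = f if fvals is None else fvals + f
    fvals = fvals / len(run_ids)
    # p-values from the mean F (identical dof across voxels, so the
    # ranking is the same monotone order as the mean F itself)
    from scipy import stats as st

    dof = prep.filtered[cutoff][run_ids[0]].shape[0] - 3
    p = st.f.sf(fvals, 1, dof)
    return fs.select_top_k(fvals, p, k)


def optimize_lowpass(prep: PreparedSession, train_runs, labels_by_run,
                     cfg: CvConfig, cache: dict | None = None) -> float:
    """Choose the low-pass cutoff minimizing inner leave-one-run-out error
    on the training runs; ties go to the lowest cutoff (strongest
    smoothing)."""
    candidates = sorted(set(cfg.lowpass_candidates))
    if len(candidates) == 1:
        return candidates[0]
    errors = {}
    for cut in candidates:
        errs = []
        for val in train_runs:
            inner = [r for r in train_runs if r != val]
            sel = _select_on_runs(prep, cut, inner, labels_by_run,
                                  cfg.k_select, cache)
            Xtr, ytr = _stack_defined(prep, cut, inner, labels_by_run)
            model = train(Xtr[:, sel], ytr, C=cfg.C)
            Xv, yv = _stack_defined(prep, cut, [val], labels_by_run)
            pred, _ = predict(model, Xv[:, sel])
            errs.append(float(np.mean(pred != yv)))
        errors[cut] = float(np.mean(errs))
    return min(candidates, key=lambda c: (errors[c], c))


def cv_predictions(prep: PreparedSession, labels_by_run, cfg: CvConfig
                   ) -> DecodingResult:
    """Leave-one-run-out CV given per-run labels (reported or permuted)."""
    n = prep.n_runs
    if n < 3:
        raise InvalidSessionError("leave-one-run-out CV needs at least 3 runs")
    recs = {k: [] for k in ("run", "vol", "true", "pred", "dec")}
    result = DecodingResult(*(np.empty(0),) * 5)
    cache: dict = {}
    for test in range(n):
        train_runs = [r for r in range(n) if r != test]
        cutoff = optimize_lowpass(prep, train_runs, labels_by_run, cfg, cache)
        sel = _select_on_runs(prep, cutoff, train_runs, labels_by_run,
                              cfg.k_select, cache)
        Xtr, ytr = _stack_defined(prep, cutoff, train_runs, labels_by_run)
        model = train(Xtr[:, sel], ytr, C=cfg.C,
                      voxel_indices=prep.retained[sel])
        lab = labels_by_run[test]
        mask = lab != 0
        pred, dec = predict(model, prep.filtered[cutoff][test][mask][:, sel])
        recs["run"].append(np.full(mask.sum(), test))
        recs["vol"].append(np.flatnonzero(mask))
        recs["true"].append(lab[mask])
        recs["pred"].append(pred)
        recs["dec"].append(dec)
        result.fold_accuracy[test] = float(np.mean(pred == lab[mask]))
        result.chosen_cutoff[test] = cutoff
        result.selected_voxels[test] = prep.retained[sel]
    result.run_index = np.concatenate(recs["run"])
    result.volume_index = np.concatenate(recs["vol"])
    result.y_true = np.concatenate(recs["true"])
    result.y_pred = np.concatenate(recs["pred"])
    result.decision = np.concatenate(recs["dec"])
    return result


def loro_cv(session: Session, cfg: CvConfig = CvConfig(),
            prep: PreparedSession | None = None) -> DecodingResult:
    """Leave-one-run-out cross-validated decoding of a session."""
    if session.n_runs < 3:
        raise InvalidSessionError("leave-one-run-out CV needs at least 3 runs")
    if prep is None:
        prep = prepare_session(session, cfg)
    return cv_predictions(prep, prep.labels, cfg)
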