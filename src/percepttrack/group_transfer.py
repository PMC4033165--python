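"""Cross-subject generalization of percept decoders.

Each subject's session is reduced to one sample per sustained-percept
interval (the mean of the three volumes around the interval center), a
per-subject weight map is trained on those samples, and subject maps are
combined by accuracy-weighted averaging:

    w_bar_k = (1/n) * sum_i 2 (p_hat_i - 1/2) w_i_k

where p_hat_i is subject i's own cross-validated accuracy.  A subject at
chance contributes nothing; a below-chance subject contributes with
flipped sign.  Transfer is evaluated leave-one-subject-out: training
subjects' maps are combined, the highest-|w_bar| voxels selected, a fresh
classifier trained on the pooled training-subject samples, and the held-out
subject scored.  All simulated subjects share one voxel grid, standing in
for normalization to a common anatomical space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import decoding, preprocessing as pp
from . import feature_selection as fs
from .core import Session
from .errors import InvalidArgumentError


@dataclass(frozen=True)
class GroupConfig:
    """Preprocessing + selection parameters for the group pipeline."""

    highpass_hz: float = 1 / 128
    lowpass_hz: float = 1 / 16
    filter_order: int = 4
    hrf_delay_s: float = 5.0
    k_subject: int = 30000   # voxels entering each subject's weight map
    k_group: int = 30000     # highest-|w_bar| voxels used for transfer
    # Heavier regularization than within-subject decoding: with interval-
    # center samples n << voxels, small C turns most samples into margin
    # violators so the weight direction averages the shared percept
    # contrast instead of per-session noise -- what map combination needs.
    C: float = 0.01
    signal_change_threshold: float = 0.10


@dataclass
class ReducedSubject:
    """Interval-center samples of one subject on the common grid."""

    X: np.ndarray            # (n_intervals, V_grid)
    y: np.ndarray            # +-1 per interval
    run_ids: np.ndarray
    switch_adjacent: np.ndarray  # True when the interval spans < 3 volumes
    retained: np.ndarray     # flat grid indices surviving exclusion
    subject_id: int = 0


@dataclass
class SubjectMap:
    """One subject's weight map embedded in the common grid."""

    w: np.ndarray
    p_hat: float
    subject_id: int

    def __post_init__(self):
        if not (0.0 <= self.p_hat <= 1.0):
            raise InvalidArgumentError("p_hat must lie in [0, 1]")


@dataclass
class GroupMap:
    w_bar: np.ndarray
    n: int
    selected_voxels: np.ndarray | None = None


def reduce_to_interval_centers(data: np.ndarray, labels: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One sample per sustained-percept interval of a run.

    Each maximal block of equal defined labels contributes the mean of the
    three volumes centered on its middle defined volume (even-length
    blocks center on the earlier of the two middle volumes; blocks
    spanning < 3 volumes contribute what they have).  Returns
    (samples, labels, switch_adjacent flags).
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    defined = np.flatnonzero(labels != 0)
    if defined.size == 0:
        raise InvalidArgumentError("run has no defined labels")
    # maximal blocks over the defined subsequence
    blocks = []
    start = 0
    for i in range(1, defined.size + 1):
        if i == defined.size or labels[defined[i]] != labels[defined[start]]:
            blocks.append(defined[start:i])
            start = i
    xs, ys, adj = [], [], []
    for vols in blocks:
        c = (len(vols) - 1) // 2
        window = vols[max(0, c - 1):c + 2]
        xs.append(data[window].mean(axis=0))
        ys.append(int(labels[vols[0]]))
        adj.append(len(vols) < 3)
    return np.vstack(xs), np.asarray(ys), np.asarray(adj)


def prepare_subject(session: Session, cfg: GroupConfig = GroupConfig(),
                    subject_id: int = 0) -> ReducedSubject:
    """Filter, label, and reduce a subject's session to interval centers.

    Columns cover the full common grid; the subject's artifact-excluded
    voxels are recorded in ``retained`` and never enter selection.
    """
    fc = pp.FilterConfig(cfg.highpass_hz, cfg.lowpass_hz, cfg.filter_order,
                         pp.ZERO_PHASE)
    retained_mask = np.ones(session.n_voxels, dtype=bool)
    mats = []
    for run in session.runs:
        mat = run.as_matrix()
        keep, _ = pp.exclude_high_signal_change_voxels(
            mat, threshold=cfg.signal_change_threshold)
        mask = np.zeros(session.n_voxels, dtype=bool)
        mask[keep] = True
        retained_mask &= mask
        mats.append(mat)
    xs, ys, adjs, rids = [], [], [], []
    for run, mat in zip(session.runs, mats):
        centered, _ = pp.zero_center(mat)
        filt = pp.bandpass(centered, session.tr, fc)
        lab = pp.labels_per_volume(run.timeline, session.tr, run.n_volumes,
                                   cfg.hrf_delay_s)
        X, y, adj = reduce_to_interval_centers(filt, lab)
        xs.append(X)
        ys.append(y)
        adjs.append(adj)
        rids.append(np.full(y.size, run.run_index))
    return ReducedSubject(X=np.vstack(xs), y=np.concatenate(ys),
                          run_ids=np.concatenate(rids),
                          switch_adjacent=np.concatenate(adjs),
                          retained=np.flatnonzero(retained_mask),
                          subject_id=subject_id)


def subject_p_hat(sub: ReducedSubject, cfg: GroupConfig = GroupConfig()
                  ) -> float:
    """Subject's own leave-one-run-out accuracy on the reduced samples,
    with top-k ANOVA selection inside each fold."""
    runs = np.unique(sub.run_ids)
    if runs.size < 2:
        raise InvalidArgumentError("p_hat needs at least 2 runs")
    correct = total = 0
    for held in runs:
        tr_mask = sub.run_ids != held
        Xtr = sub.X[tr_mask][:, sub.retained]
        ytr = sub.y[tr_mask]
        if np.unique(ytr).size < 2:
            continue
        f, p = fs.anova_scores(Xtr, ytr)
        sel = fs.select_top_k(f, p, min(cfg.k_subject, sub.retained.size))
        model = decoding.train(Xtr[:, sel], ytr, C=cfg.C)
        Xte = sub.X[~tr_mask][:, sub.retained][:, sel]
        pred, _ = decoding.predict(model, Xte)
        correct += int(np.sum(pred == sub.y[~tr_mask]))
        total += pred.size
    return correct / total if total else 0.5


def subject_weight_map(sub: ReducedSubject, grid_size: int,
                       cfg: GroupConfig = GroupConfig(),
                       p_hat: float | None = None) -> SubjectMap:
    """Train on all of a subject's reduced samples (top-k ANOVA selection)
    and embed the weights into the common grid (zeros elsewhere)."""
    if p_hat is None:
        p_hat = subject_p_hat(sub, cfg)
    Xr = sub.X[:, sub.retained]
    f, p = fs.anova_scores(Xr, sub.y)
    sel = fs.select_top_k(f, p, min(cfg.k_subject, sub.retained.size))
    model = decoding.train(Xr[:, sel], sub.y, C=cfg.C)
    w_full = np.zeros(grid_size)
    w_full[sub.retained[sel]] = model.w
    return SubjectMap(w=w_full, p_hat=p_hat, subject_id=sub.subject_id)


def combine_weight_maps(maps: list[SubjectMap]) -> GroupMap:
    """Accuracy-weighted average: w_bar = (1/n) sum_i 2 (p_hat_i - 1/2) w_i."""
    if not maps:
        raise InvalidArgumentError("need at least one subject map")
    size = maps[0].w.size
    for m in maps:
        if m.w.size != size:
            raise InvalidArgumentError("subject maps must share the grid")
    w_bar = np.zeros(size)
    for m in maps:
        w_bar += 2.0 * (m.p_hat - 0.5) * m.w
    w_bar /= len(maps)
    return GroupMap(w_bar=w_bar, n=len(maps))


@dataclass
class TransferFold:
    subject_id: int
    accuracy: float
    accuracy_away: float
    n_samples: int
    y_true: np.ndarray
    y_pred: np.ndarray
    switch_adjacent: np.ndarray


def loso_cv(subjects: list[ReducedSubject],
            cfg: GroupConfig = GroupConfig()) -> list[TransferFold]:
    """Leave-one-subject-out transfer evaluation.

    Per fold: combine the training subjects' maps, select the k_group
    highest-|w_bar| voxels, train a fresh classifier on the pooled training
    samples restricted to those voxels, and score the held-out subject.
    The held-out subject contributes nothing to map combination or voxel
    selection.
    """
    if len(subjects) < 3:
        raise InvalidArgumentError("leave-one-subject-out needs >= 3 subjects")
    grid = subjects[0].X.shape[1]
    maps = {s.subject_id: subject_weight_map(s, grid, cfg) for s in subjects}
    folds = []
    for held in subjects:
        train_subs = [s for s in subjects if s.subject_id != held.subject_id]
        group = combine_weight_maps([maps[s.subject_id] for s in train_subs])
        k = min(cfg.k_group, grid)
        sel = np.argsort(-np.abs(group.w_bar), kind="stable")[:k]
        Xtr = np.vstack([s.X[:, sel] for s in train_subs])
        ytr = np.concatenate([s.y for s in train_subs])
        model = decoding.train(Xtr, ytr, C=cfg.C)
        pred, _ = decoding.predict(model, held.X[:, sel])
        away = ~held.switch_adjacent
        acc_away = float(np.mean(pred[away] == held.y[away])) if away.any() else np.nan
        folds.append(TransferFold(
            subject_id=held.subject_id,
            accuracy=float(np.mean(pred == held.y)),
            accuracy_away=acc_away,
            n_samples=held.y.size,
            y_true=held.y, y_pred=pred,
            switch_adjacent=held.switch_adjacent))
    return folds


def transfer_guessing_ci(y_true: np.ndarray, y_pred: np.ndarray,
                         n_perm: int = 500, alpha: float = 0.05,
                         rng: np.random.Generator | None = None
                         ) -> tuple[float, float]:
    """Guessing CI for a fixed prediction sequence: block-permute the true
    labels and recompute accuracy."""
    from .permutation_stats import block_permute

    rng = np.random.default_rng(0) if rng is None else rng
    accs = np.empty(n_perm)
    for i in range(n_perm):
        accs[i] = np.mean(block_permute(y_true, rng) == y_pred)
    lo, hi = np.percentile(accs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
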