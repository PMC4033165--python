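"""Voxel ranking by percept discriminability and top-K retention.

Ranking fits, per voxel, an ordinary least squares GLM with HRF-convolved
boxcar regressors for the two percepts plus an intercept, and scores the
contrast (object amplitude - line amplitude) with an F test.  With two
conditions this F is identical to a one-way ANOVA, so the same code path
serves both the offline "F-test" and online "ANOVA" descriptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (LABEL_OF_STATE, LINE, OBJECT, STATE_OF_LABEL, Interval,
                   PerceptTimeline)
from .errors import DegenerateDesignError, EmptySelectionError
from .synthetic_data import bold_response

log = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """GLM design: columns [line_regressor, object_regressor, intercept]."""

    X: np.ndarray  # (T, 3)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class RefineConfig:
    """Second-pass multivariate refinement: keep voxels whose absolute
    classifier weight exceeds threshold_factor * max |w|."""

    threshold_factor: float = 0.1

    def __post_init__(self):
        if not (0 < self.threshold_factor < 1):
            raise DegenerateDesignError("threshold_factor must lie in (0, 1)")


def build_design(timeline: PerceptTimeline, tr: float,
                 n_volumes: int) -> DesignMatrix:
    """Per-state boxcars convolved with the canonical HRF, sampled at the
    volume grid, plus an intercept column."""
    states = set(timeline.states())
    if len(states) < 2:
        raise DegenerateDesignError(
            "timeline contains a single state; percept contrast undefined")
    line = bold_response(timeline, tr, n_volumes, state=LINE)
    obj = bold_response(timeline, tr, n_volumes, state=OBJECT)
    X = np.column_stack([line, obj, np.ones(n_volumes)])
    return DesignMatrix(X)


def timeline_from_labels(labels: np.ndarray, tr: float,
                         hrf_delay: float = 5.0) -> PerceptTimeline:
    """Reconstruct a percept timeline from shifted per-volume labels.

    Inverts the hemodynamic label shift: a block of equal labels starting
    at volume k0 corresponds to a state interval beginning at k0*TR - delay
    in stimulus time (clipped at 0).  Used so that permuted label sequences
    can be scored through exactly the same GLM machinery as reported ones.
    """
    n = labels.size
    defined = np.flatnonzero(labels != 0)
    if defined.size == 0:
        raise DegenerateDesignError("no defined labels")
    edges = [int(defined[0])]
    prev = labels[defined[0]]
    for i in defined[1:]:
        if labels[i] != prev:
            edges.append(int(i))
            prev = labels[i]
    onsets, states = [], []
    for k0 in edges:
        st = STATE_OF_LABEL[labels[k0]]
        if states and states[-1] == st:
            continue  # adjacent equal-label blocks merge
        onsets.append(max(0.0, k0 * tr - hrf_delay))
        states.append(st)
    onsets[0] = 0.0  # the first block's state extends back to run start
    total = n * tr
    intervals = []
    for i, (on, st) in enumerate(zip(onsets, states)):
        end = onsets[i + 1] if i + 1 < len(onsets) else total
        intervals.append(Interval(on, end - on, st))
    return PerceptTimeline(tuple(intervals), total)


def design_from_labels(labels: np.ndarray, tr: float,
                       hrf_delay: float = 5.0) -> DesignMatrix:
    """Design matrix built from shifted per-volume labels (see
    :func:`timeline_from_labels`)."""
    return build_design(timeline_from_labels(labels, tr, hrf_delay),
                        tr, labels.size)


def univariate_scores(data: np.ndarray, design: DesignMatrix
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel GLM contrast F (object - line) and p-value.

    OLS via the pseudoinverse; the F statistic equals the squared contrast
    t with (1, T - rank(X)) degrees of freedom.  The contrast is estimable
    even when the two convolved boxcars sum to a near-constant column.
    """
    X = design.X
    Y = np.asarray(data, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise DegenerateDesignError(
            f"data has {Y.shape[0]} rows but design has {X.shape[0]}")
    if Y.shape[0] <= X.shape[1]:
        raise DegenerateDesignError("need more rows than design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < 2:
        raise DegenerateDesignError("design matrix is rank deficient")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = Y.shape[0] - rank
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    c = np.array([-1.0, 1.0, 0.0])
    cvar = float(c @ pinv @ pinv.T @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * cvar)
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    f = t ** 2
    p = stats.f.sf(f, 1, dof)
    return f, p


def anova_scores(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-class one-way ANOVA F per column, for unordered sample sets
    (e.g. interval-center samples) where no HRF model applies.

    Identical to the squared pooled-variance two-sample t with
    (1, n - 2) degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    a, b = X[y == LABEL_OF_STATE[OBJECT]], X[y == LABEL_OF_STATE[LINE]]
    na, nb = a.shape[0], b.shape[0]
    if na == 0 or nb == 0:
        raise DegenerateDesignError("both classes must be present")
    dof = na + nb - 2
    pooled = ((a.var(axis=0, ddof=1) * (na - 1) +
               b.var(axis=0, ddof=1) * (nb - 1)) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / \
            np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    f = t ** 2
    return f, stats.f.sf(f, 1, dof)


def select_top_k(f: np.ndarray, p: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest p-values, best first.

    Ties broken by larger F, then lower voxel index.  If fewer than k
    voxels are available all are returned (with a logged warning).
    """
    if k < 1:
        raise EmptySelectionError("k must be >= 1")
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    n = p.size
    if k > n:
        log.warning("requested top %d of only %d voxels; returning all", k, n)
        k = n
    order = np.lexsort((np.arange(n), -f, p))
    return order[:k]


def multivariate_refine(w: np.ndarray,
                        cfg: RefineConfig = RefineConfig()) -> np.ndarray:
    """Keep positions with |w| strictly above threshold_factor * max |w|.

    All-equal weights survive in full (no weight strictly exceeds the
    threshold's complement set); an all-zero weight vector is an error.
    """
    w = np.abs(np.asarray(w, dtype=float))
    wmax = w.max() if w.size else 0.0
    if wmax == 0.0:
        raise EmptySelectionError("cannot refine an all-zero weight vector")
    keep = np.flatnonzero(w > cfg.threshold_factor * wmax)
    return keep


def scores_table(f: np.ndarray, p: np.ndarray,
                 grid_shape: tuple[int, int, int],
                 voxel_indices: np.ndarray | None = None):
    """Per-voxel score table (voxel, x, y, z, F, p) as a DataFrame."""
    import pandas as pd

    idx = np.arange(p.size) if voxel_indices is None else np.asarray(voxel_indices)
    x, y, z = np.unravel_index(idx, grid_shape)
    return pd.DataFrame({"voxel": idx, "x": x, "y": y, "z": z, "F": f, "p": p})
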