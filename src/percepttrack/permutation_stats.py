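"""Block-preserving permutation nulls for accuracies and classifier weights.

Percept labels in a BOLD time series are strongly autocorrelated: states
persist for many volumes.  Naive label shuffling destroys this structure
and produces an over-optimistic chance distribution, so permutations here
shuffle *full blocks* of consecutively equal labels, preserving the
multiset of block lengths and the per-label volume counts.  Blocks are
formed within runs (a block never straddles a run boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import decoding
from .core import Session
from .errors import InvalidArgumentError


@dataclass
class PermutationNull:
    """Null distribution of a statistic under block permutation."""

    values: np.ndarray
    observed: float
    n_permutations: int
    alpha: float = 0.05

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.values,
                               [100 * self.alpha / 2, 100 * (1 - self.alpha / 2)])
        return float(lo), float(hi)

    def observed_inside_ci(self) -> bool:
        lo, hi = self.ci
        return lo <= self.observed <= hi


@dataclass
class WeightSignificance:
    """Per-voxel permutation p-values for classifier weights."""

    p_w: np.ndarray
    n_permutations: int


def label_blocks(labels: np.ndarray) -> list[tuple[int, int]]:
    """Decompose a label sequence into maximal (label, length) blocks."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidArgumentError("labels must be non-empty")
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def block_permute(labels: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Uniformly shuffle the order of maximal constant blocks.

    Adjacent equal-label blocks in the output may merge; per-label volume
    counts and the block-length multiset are preserved exactly.
    """
    blocks = label_blocks(labels)
    order = rng.permutation(len(blocks))
    out = np.concatenate([np.full(blocks[i][1], blocks[i][0]) for i in order])
    return out


def block_permute_defined(labels_by_run: list[np.ndarray],
                          rng: np.random.Generator) -> list[np.ndarray]:
    """Session-wide block permutation of defined labels.

    Blocks are formed per run over the defined (non-zero) labels, the whole
    collection is shuffled, and the permuted sequence is redistributed into
    the runs' defined positions; undefined positions stay undefined.
    """
    blocks = []
    for lab in labels_by_run:
        defined = lab[lab != 0]
        if defined.size:
            blocks.extend(label_blocks(defined))
    order = rng.permutation(len(blocks))
    flat = np.concatenate([np.full(blocks[i][1], blocks[i][0]) for i in order])
    out = []
    pos = 0
    for lab in labels_by_run:
        new = lab.copy()
        idx = np.flatnonzero(lab != 0)
        new[idx] = flat[pos:pos + idx.size]
        pos += idx.size
        out.append(new)
    return out


def guessing_level_ci(session: Session,
                      cfg: decoding.CvConfig = decoding.CvConfig(),
                      n_perm: int = 500, alpha: float = 0.05,
                      rng: np.random.Generator | None = None,
                      prep: decoding.PreparedSession | None = None
                      ) -> PermutationNull:
    """Empirical guessing level of the full cross-validated decoder.

    Each permutation block-permutes the session's labels and reruns the
    complete leave-one-run-out CV, including univariate feature selection
    inside every fold, recording the pooled accuracy.  The observed
    (unpermuted) accuracy is stored alongside the null for CI comparison.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    if prep is None:
        prep = decoding.prepare_session(session, cfg)
    observed = decoding.cv_predictions(prep, prep.labels, cfg).accuracy
    values = np.empty(n_perm)
    for i in range(n_perm):
        permuted = block_permute_defined(prep.labels, rng)
        values[i] = decoding.cv_predictions(prep, permuted, cfg).accuracy
    return PermutationNull(values=values, observed=observed,
                           n_permutations=n_perm, alpha=alpha)


def weight_significance(X: np.ndarray, y: np.ndarray, n_perm: int = 1000,
                        C: float = 1.0,
                        rng: np.random.Generator | None = None
                        ) -> WeightSignificance:
    """Permutation p-value p_w for each voxel's classifier weight.

    p_w(k) = #{permutations with |w_perm,k| >= |w_obs,k|} / n_perm,
    with ties counting as exceeding (the conservative choice) and each
    weight vector normalized to unit Euclidean norm before comparison.
    Normalization is essential: the decision rule is invariant to a common
    rescaling of w and b, and the *overall* weight norm shrinks as class
    separation grows, so comparing raw weights would paradoxically make
    strongly informative voxels look less significant.  Low p_w marks
    voxels that carry a larger share of the discriminative pattern than
    chance relabelings produce.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    y = np.asarray(y)

    def unit_weights(labels):
        w = decoding.train(X, labels, C=C).w
        return np.abs(w) / np.linalg.norm(w)

    w_obs = unit_weights(y)
    count = np.zeros(w_obs.size)
    for _ in range(n_perm):
        y_perm = block_permute(y, rng)
        if np.unique(y_perm).size < 2:  # degenerate shuffle; resample
            y_perm = block_permute(y, rng)
        count += unit_weights(y_perm) >= w_obs
    return WeightSignificance(p_w=count / n_perm, n_permutations=n_perm)


def conjunction_mask(sig_a: WeightSignificance | np.ndarray,
                     sig_b: WeightSignificance | np.ndarray,
                     threshold: float = 0.1) -> np.ndarray:
    """Voxels significant (p_w < threshold, strict) in BOTH experiments."""
    pa = sig_a.p_w if isinstance(sig_a, WeightSignificance) else np.asarray(sig_a)
    pb = sig_b.p_w if isinstance(sig_b, WeightSignificance) else np.asarray(sig_b)
    if pa.shape != pb.shape:
        raise InvalidArgumentError("weight-significance grids do not match")
    return (pa < threshold) & (pb < threshold)
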