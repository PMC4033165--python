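"""Accuracy decompositions, dwell-time gamma fits, t-maps and reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import LABEL_OF_STATE, STATES, PerceptTimeline
from .errors import InvalidArgumentError

MLE = "mle"
HISTOGRAM_LS = "histogram_ls"


@dataclass
class GammaFit:
    shape: float
    scale: float
    method: str
    r_squared: float | None = None

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise InvalidArgumentError("fitted shape and scale must be > 0")


def switch_local_accuracy(y_true: np.ndarray, y_pred: np.ndarray,
                          run_index: np.ndarray | None = None
                          ) -> tuple[float, float, float]:
    """(overall, away-from-switch, near-switch) accuracies.

    A switch volume is the first volume of a new true state within a run;
    the near-switch set is each switch volume plus one neighbor on either
    side.  The two subsets partition the volumes, so the overall accuracy
    is their size-weighted mean.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise InvalidArgumentError("empty result")
    if run_index is None:
        run_index = np.zeros(y_true.size, dtype=int)
    near = np.zeros(y_true.size, dtype=bool)
    for r in np.unique(run_index):
        idx = np.flatnonzero(run_index == r)
        yt = y_true[idx]
        switches = np.flatnonzero(np.diff(yt) != 0) + 1
        for s in switches:
            near[idx[max(0, s - 1):s + 2]] = True
    correct = y_true == y_pred
    overall = float(correct.mean())
    away = float(correct[~near].mean()) if (~near).any() else np.nan
    nearacc = float(correct[near].mean()) if near.any() else np.nan
    return overall, away, nearacc


def fit_gamma(durations, method: str = MLE, bin_width: float = 3.0) -> GammaFit:
    """Fit a two-parameter gamma to dwell durations.

    ``mle``: maximum likelihood with location fixed at 0.
    ``histogram_ls``: least-squares fit of the gamma pdf to the normalized
    duration histogram, with the R-squared of the fit reported.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 10:
        raise InvalidArgumentError("need at least 10 durations")
    if (d <= 0).any():
        raise InvalidArgumentError("durations must be positive")
    if np.ptp(d) == 0:
        raise InvalidArgumentError(
            "all durations equal: the gamma MLE is degenerate; "
            "check that dwell times were recorded with real variability")
    if method == MLE:
        shape, _, scale = stats.gamma.fit(d, floc=0)
        return GammaFit(shape=float(shape), scale=float(scale), method=MLE)
    if method == HISTOGRAM_LS:
        edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
        dens, edges = np.histogram(d, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean, var = d.mean(), d.var()
        p0 = (mean ** 2 / var, var / mean)
        popt, _ = optimize.curve_fit(
            lambda x, a, b: stats.gamma.pdf(x, a, scale=b),
            centers, dens, p0=p0, maxfev=10000)
        fitted = stats.gamma.pdf(centers, popt[0], scale=popt[1])
        ss_res = float(np.sum((dens - fitted) ** 2))
        ss_tot = float(np.sum((dens - dens.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return GammaFit(shape=float(popt[0]), scale=float(popt[1]),
                        method=HISTOGRAM_LS, r_squared=r2)
    raise InvalidArgumentError(f"unknown method {method!r}")


def gamma_mode(fit: GammaFit | tuple[float, float]) -> float:
    """Mode of the gamma pdf: (shape - 1) * scale for shape > 1, else 0."""
    shape, scale = (fit.shape, fit.scale) if isinstance(fit, GammaFit) else fit
    return (shape - 1.0) * scale if shape > 1.0 else 0.0


def gamma_mode_grid(shape: float, scale: float, t_max: float = 60.0,
                    dt: float = 0.01) -> float:
    """Mode by dense grid maximization of the pdf (cross-check of the
    closed form)."""
    t = np.arange(0.0, t_max + dt, dt)
    return float(t[np.argmax(stats.gamma.pdf(t, shape, scale=scale))])


def duration_stats(timelines: list[PerceptTimeline],
                   query_delay: float | None = None) -> dict:
    """Pooled dwell summary: median, per-state time proportions, and the
    empirical CDF at a query delay (fraction of dwell times shorter)."""
    if not timelines:
        raise InvalidArgumentError("need at least one timeline")
    durations = np.concatenate([tl.durations() for tl in timelines])
    per_state = {s: 0.0 for s in STATES}
    for tl in timelines:
        for iv in tl.intervals:
            per_state[iv.state] += iv.duration
    total = sum(per_state.values())
    out = {
        "median_s": float(np.median(durations)),
        "proportion": {s: per_state[s] / total for s in STATES},
        "n_intervals": int(durations.size),
    }
    if query_delay is not None:
        out["fraction_shorter_than_delay"] = float(np.mean(durations < query_delay))
    return out


def signed_tmap(X: np.ndarray, y: np.ndarray,
                mask: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Per-voxel two-sample t (object minus line), pooled variance.

    Positive t means higher BOLD signal during object percepts.  Returns
    (t values, degrees of freedom).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    a = X[y == LABEL_OF_STATE["OBJECT"]]
    b = X[y == LABEL_OF_STATE["LINE"]]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise InvalidArgumentError("both percept classes must be present")
    t, _ = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    if mask is not None:
        t = np.where(mask, t, 0.0)
    return t, a.shape[0] + b.shape[0] - 2


def critical_t(alpha_two_sided: float, df: int) -> float:
    """Two-sided Student-t critical value: inverse CDF at 1 - alpha/2."""
    if not (0 < alpha_two_sided < 1):
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    if df < 1:
        raise InvalidArgumentError("df must be >= 1")
    return float(stats.t.ppf(1.0 - alpha_two_sided / 2.0, df))


def save_map_nifti(values: np.ndarray, grid_shape: tuple[int, int, int],
                   path) -> None:
    """Write a per-voxel map (flat, C order) as a 3D NIfTI volume —
    used for t-maps, weight maps, p_w maps and conjunction masks."""
    import nibabel as nib

    vol = np.asarray(values, dtype=np.float32).reshape(grid_shape)
    nib.Nifti1Image(vol, affine=np.eye(4)).to_filename(str(path))


def plot_duration_histogram(durations, fit: GammaFit | None = None,
                            bin_width: float = 3.0, path=None):
    """Duration histogram with an optional fitted gamma pdf overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = np.asarray(durations, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    ax.hist(d, bins=edges, density=True, color="0.7", edgecolor="0.4")
    if fit is not None:
        t = np.linspace(0, d.max() * 1.1, 300)
        ax.plot(t, stats.gamma.pdf(t, fit.shape, scale=fit.scale), "k-",
                label=f"gamma(shape={fit.shape:.2f}, scale={fit.scale:.2f})")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("dwell time (s)")
    ax.set_ylabel("density")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_decision_timecourse(decision, y_true, y_pred, tr: float, path=None):
    """Decision-value time course with correct/incorrect volume markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    decision = np.asarray(decision, dtype=float)
    t = np.arange(decision.size) * tr
    ok = np.asarray(y_true) == np.asarray(y_pred)
    fig, ax = plt.subplots(figsize=(7, 2.8))
    ax.plot(t, decision, "-", color="0.6", lw=0.8)
    ax.plot(t[ok], decision[ok], "o", ms=3, color="tab:blue", label="correct")
    ax.plot(t[~ok], decision[~ok], "x", ms=4, color="tab:red", label="error")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("distance to hyperplane")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
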