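"""Core containers shared by every pipeline stage.

Perceptual states are the two mutually exclusive interpretations of the
ambiguous slit-viewing stimulus: vertically moving line segments (``LINE``)
or an integrated object moving horizontally behind the aperture
(``OBJECT``).  Classifier labels map ``OBJECT`` to +1 and ``LINE`` to -1;
label 0 marks volumes whose percept is undefined (e.g. the first volumes of
a run, before the hemodynamic-delay-shifted report window enters the run).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

LINE = "LINE"
OBJECT = "OBJECT"
STATES = (LINE, OBJECT)

#: per-volume classifier labels
LABEL_LINE = -1
LABEL_OBJECT = +1
LABEL_UNDEFINED = 0

LABEL_OF_STATE = {LINE: LABEL_LINE, OBJECT: LABEL_OBJECT}
STATE_OF_LABEL = {LABEL_LINE: LINE, LABEL_OBJECT: OBJECT}


def other_state(state: str) -> str:
    return OBJECT if state == LINE else LINE


@dataclass(frozen=True)
class Interval:
    """One uninterrupted perceptual state: [onset, onset + duration) seconds."""

    onset: float
    duration: float
    state: str

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class PerceptTimeline:
    """Contiguous alternating percept intervals covering [0, total_duration).

    Invariants (checked on construction): intervals are contiguous and
    non-overlapping, cover the full duration, have strictly positive
    durations, and consecutive intervals carry different states.
    """

    intervals: tuple[Interval, ...]
    total_duration: float

    def __post_init__(self):
        if not self.intervals:
            raise InvalidArgumentError("timeline needs at least one interval")
        t = 0.0
        prev_state = None
        for iv in self.intervals:
            if iv.state not in STATES:
                raise InvalidArgumentError(f"unknown state {iv.state!r}")
            if iv.duration <= 0:
                raise InvalidArgumentError("interval durations must be > 0")
            if abs(iv.onset - t) > 1e-9:
                raise InvalidArgumentError("intervals must be contiguous")
            if iv.state == prev_state:
                raise InvalidArgumentError("consecutive intervals must alternate states")
            prev_state = iv.state
            t = iv.end
        if abs(t - self.total_duration) > 1e-9:
            raise InvalidArgumentError("intervals must cover [0, total_duration)")

    def durations(self) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals])

    def states(self) -> list[str]:
        return [iv.state for iv in self.intervals]

    def state_at(self, t: float) -> str:
        """State occupying time t (clamped to the timeline's support)."""
        t = min(max(t, 0.0), self.total_duration - 1e-12)
        for iv in self.intervals:
            if iv.onset <= t < iv.end:
                return iv.state
        return self.intervals[-1].state

    @classmethod
    def from_durations(cls, durations: Sequence[float], first_state: str,
                       total_duration: float | None = None) -> "PerceptTimeline":
        intervals = []
        t, state = 0.0, first_state
        for d in durations:
            intervals.append(Interval(t, d, state))
            t += d
            state = other_state(state)
        return cls(tuple(intervals), total_duration if total_duration is not None else t)


@dataclass
class Run:
    """One acquisition run: a 4D voxel grid (X, Y, Z, T) with its TR and the
    percept report timeline attached as ground truth."""

    data: np.ndarray
    tr: float
    run_index: int
    timeline: PerceptTimeline

    def __post_init__(self):
        if self.data.ndim != 4:
            raise InvalidArgumentError("run data must be 4-dimensional (X, Y, Z, T)")
        if self.tr <= 0:
            raise InvalidArgumentError("tr must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        x, y, z = self.grid_shape
        return x * y * z

    def as_matrix(self) -> np.ndarray:
        """(T, V) view of the run, voxels flattened in C order."""
        return self.data.reshape(self.n_voxels, self.n_volumes).T


@dataclass
class Session:
    """An ordered collection of runs sharing TR and voxel grid."""

    runs: list[Run]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.runs:
            raise InvalidArgumentError("session needs at least one run")
        tr = self.runs[0].tr
        shape = self.runs[0].grid_shape
        for r in self.runs:
            if abs(r.tr - tr) > 1e-9 or r.grid_shape != shape:
                raise InvalidArgumentError("runs must share TR and grid shape")

    @property
    def tr(self) -> float:
        return self.runs[0].tr

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.runs[0].grid_shape

    @property
    def n_voxels(self) -> int:
        return self.runs[0].n_voxels


@dataclass
class LinearModel:
    """Linear max-margin decision rule: label = sign(w . x + b).

    ``voxel_indices`` maps each weight back to a flat index into the voxel
    grid, so weight maps can be re-embedded into volume space.
    """

    w: np.ndarray
    b: float
    voxel_indices: np.ndarray
    C: float = 1.0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.w.shape != self.voxel_indices.shape:
            raise InvalidArgumentError("w and voxel_indices must have equal length")

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": self.b,
            "voxel_indices": self.voxel_indices.tolist(),
            "C": self.C,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(np.asarray(d["w"]), float(d["b"]),
                   np.asarray(d["voxel_indices"]), float(d.get("C", 1.0)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "LinearModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
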