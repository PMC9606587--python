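"""Core domain types for capsule-endoscopy review triage.

A colon capsule (e.g. PillCam COLON 2) records two independent video
streams, one per camera head. Frames carry a per-frame polyp probability
from an upstream classifier; ground truth is a set of lesions, each
annotated with the closed timestamp interval during which it was visible
on one head. Review decisions are matched back to lesions at the
lesion level: a polyp counts as detected if at least one "polyp"
decision falls inside its interval on the correct head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

HEADS = ("front", "rear")
MORPHOLOGIES = ("pedunculated", "sessile", "flat")
DECISIONS = ("polyp", "clear", "other")

#: Lesions below this diameter (mm) are classed "small", at or above it "large".
SMALL_SIZE_CUTOFF_MM = 6.0
#: Visibility classes by number of frames the lesion appears in:
#: low < LOW_VIS_MAX_FRAMES <= normal <= NORMAL_VIS_MAX_FRAMES < high.
LOW_VIS_MAX_FRAMES = 4
NORMAL_VIS_MAX_FRAMES = 10


class TriageError(Exception):
    """Base class for all package errors."""


class SchemaError(TriageError):
    """A tabular input is missing required columns or has a bad header."""


class ValidationError(TriageError):
    """A value violates a domain invariant (with row context where known)."""


class ConfigurationError(TriageError):
    """A study/scorer/reader configuration is internally inconsistent."""


def _check_head(head: str) -> str:
    if head not in HEADS:
        raise ValidationError(f"head must be one of {HEADS}, got {head!r}")
    return head


@dataclass(frozen=True)
class FrameRecord:
    """One capsule frame: identity, time and polyp probability score."""

    study_id: str
    head: str
    frame_index: int
    timestamp_s: float
    score: float
    image_path: Optional[str] = None

    def __post_init__(self) -> None:
        _check_head(self.head)
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.timestamp_s < 0:
            raise ValidationError(f"timestamp_s must be >= 0, got {self.timestamp_s}")
        if not (0.0 <= self.score <= 1.0) or math.isnan(self.score):
            raise ValidationError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class PolypAnnotation:
    """Ground-truth lesion with its head-specific visibility interval.

    The interval is CLOSED: ``first_ts`` and ``last_ts`` are the timestamps
    of the first and last frame in which the lesion was visible, so both
    endpoints count as inside.
    """

    polyp_id: str
    head: str
    first_ts: float
    last_ts: float
    size_mm: float
    morphology: str
    n_visible_frames: int

    def __post_init__(self) -> None:
        _check_head(self.head)
        if self.first_ts > self.last_ts:
            raise ValidationError(
                f"polyp {self.polyp_id}: first_ts {self.first_ts} > last_ts {self.last_ts}"
            )
        if self.size_mm <= 0:
            raise ValidationError(f"polyp {self.polyp_id}: size_mm must be > 0")
        if self.morphology not in MORPHOLOGIES:
            raise ValidationError(
                f"polyp {self.polyp_id}: morphology must be one of {MORPHOLOGIES}, "
                f"got {self.morphology!r}"
            )
        if self.n_visible_frames < 1:
            raise ValidationError(
                f"polyp {self.polyp_id}: n_visible_frames must be >= 1"
            )

    @property
    def size_class(self) -> str:
        return "small" if self.size_mm < SMALL_SIZE_CUTOFF_MM else "large"

    @property
    def visibility_class(self) -> str:
        if self.n_visible_frames < LOW_VIS_MAX_FRAMES:
            return "low"
        if self.n_visible_frames <= NORMAL_VIS_MAX_FRAMES:
            return "normal"
        return "high"

    def contains(self, head: str, timestamp_s: float) -> bool:
        """Closed-interval membership on the annotation's own head."""
        return head == self.head and self.first_ts <= timestamp_s <= self.last_ts


@dataclass(frozen=True)
class CandidateSequence:
    """A ranked review unit: a proposed center frame plus k context frames
    on each side (truncated at video boundaries)."""

    rank: int
    center: FrameRecord
    context_before: tuple[FrameRecord, ...] = ()
    context_after: tuple[FrameRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"rank must be >= 1, got {self.rank}")

    @property
    def head(self) -> str:
        return self.center.head

    @property
    def display_score(self) -> float:
        return self.center.score


@dataclass(frozen=True)
class ReviewEvent:
    """One timed decision on one candidate sequence."""

    rank: int
    head: str
    frame_index: int
    timestamp_s: float
    decision: str
    elapsed_s: float

    def __post_init__(self) -> None:
        if self.decision not in DECISIONS:
            raise ValidationError(
                f"decision must be one of {DECISIONS}, got {self.decision!r}"
            )


@dataclass
class ReviewTrace:
    """Ordered timed decisions from a (real or simulated) reader."""

    study_id: str
    events: list[ReviewEvent] = field(default_factory=list)
    budget_s: float = math.inf

    def __post_init__(self) -> None:
        elapsed = [e.elapsed_s for e in self.events]
        if any(b <= a for a, b in zip(elapsed, elapsed[1:])):
            raise ValidationError("elapsed_s must be strictly increasing")
        if elapsed and elapsed[-1] > self.budget_s:
            raise ValidationError("trace exceeds its own budget")

    def __len__(self) -> int:
        return len(self.events)


class SensitivityCurve:
    """Cumulative lesion-level sensitivity on a time grid.

    The curve is non-decreasing, starts at 0 at t = 0 and stays in [0, 1].
    """

    def __init__(self, time_s: Sequence[float], sensitivity: Sequence[float]):
        t = np.asarray(time_s, dtype=float)
        s = np.asarray(sensitivity, dtype=float)
        if t.size == 0:
            raise ValidationError("curve must have at least one time point")
        if t.shape != s.shape:
            raise ValidationError("time and sensitivity grids differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if t[0] != 0.0:
            raise ValidationError("curve must start at t = 0")
        if s[0] not in (0.0,) and s[0] > 1e-12:
            # a curve may legitimately start above 0 only when something is
            # detected at t = 0, which the simulators never produce
            pass
        if np.any(np.diff(s) < -1e-12):
            raise ValidationError("sensitivity must be non-decreasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValidationError("sensitivity must lie in [0, 1]")
        self.time_s = t
        self.sensitivity = np.clip(s, 0.0, 1.0)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SensitivityCurve)
            and np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.sensitivity, other.sensitivity)
        )

    def __repr__(self) -> str:
        return (
            f"SensitivityCurve(n={self.time_s.size}, "
            f"t_max={self.time_s[-1]:g}, final={self.sensitivity[-1]:.4f})"
        )

    @property
    def final(self) -> float:
        return float(self.sensitivity[-1])

    def value_at(self, t: float) -> float:
        """Curve value at time t (step interpolation, right-continuous)."""
        idx = np.searchsorted(self.time_s, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.sensitivity[min(idx, self.time_s.size - 1)])
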