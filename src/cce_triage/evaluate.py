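"""Lesion-level evaluation of review traces.

A lesion counts as detected when at least one "polyp" decision falls on
its head with a timestamp inside the closed visibility interval
[first_ts, last_ts]. On top of that matching rule the module builds the
standard outputs of a triage reading study: sensitivity stratified by
lesion size, visibility and morphology; cumulative sensitivity as a step
function of elapsed review time (averaged across studies with equal
weight); the Super-Expert curve — the upper bound achieved by a reader
who recognizes every shown true lesion and makes no false calls; the
time-to-parity at which a curve reaches a reference sensitivity; and the
resulting speed-up factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    CandidateSequence,
    PolypAnnotation,
    ReviewTrace,
    SensitivityCurve,
    TriageError,
    ValidationError,
)
from .synthetic import SUPER_EXPERT, ReaderParams, simulate_reader

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionVerdict:
    polyp_id: str
    detected: bool
    first_detection_time_s: Optional[float]  # elapsed review time, not video time


def match_detections(
    trace: ReviewTrace, annotations: Sequence[PolypAnnotation]
) -> dict[str, DetectionVerdict]:
    """Match "polyp" decisions to lesions by head and closed interval.

    "clear" and "other" decisions never count as detections. Returns one
    verdict per annotation; ``first_detection_time_s`` is the earliest
    elapsed time of a matching decision.
    """
    polyp_events = [e for e in trace.events if e.decision == "polyp"]
    verdicts: dict[str, DetectionVerdict] = {}
    for ann in annotations:
        times = [
            e.elapsed_s
            for e in polyp_events
            if ann.contains(e.head, e.timestamp_s)
        ]
        verdicts[ann.polyp_id] = DetectionVerdict(
            polyp_id=ann.polyp_id,
            detected=bool(times),
            first_detection_time_s=min(times) if times else None,
        )
    return verdicts


_STRATA = [
    ("size", "small"),
    ("size", "large"),
    ("visibility", "low"),
    ("visibility", "normal"),
    ("visibility", "high"),
    ("morphology", "pedunculated"),
    ("morphology", "sessile"),
    ("morphology", "flat"),
]


def stratified_sensitivity(
    verdicts: dict[str, DetectionVerdict],
    annotations: Sequence[PolypAnnotation],
) -> pd.DataFrame:
    """Per-stratum detected/total as a percentage, plus an overall row.

    Denominators are per-lesion counts from the provided annotations.
    Empty strata report n_polyps = 0 with a null sensitivity.
    """
    missing = [a.polyp_id for a in annotations if a.polyp_id not in verdicts]
    if missing:
        raise ValidationError(f"no verdict for polyp(s): {', '.join(missing)}")

    def _label(ann: PolypAnnotation, category: str) -> str:
        return {
            "size": ann.size_class,
            "visibility": ann.visibility_class,
            "morphology": ann.morphology,
        }[category]

    rows = []
    for category, label in _STRATA:
        members = [a for a in annotations if _label(a, category) == label]
        n = len(members)
        detected = sum(verdicts[a.polyp_id].detected for a in members)
        rows.append(
            {
                "category": category,
                "label": label,
                "n_polyps": n,
                "sensitivity_pct": round(100.0 * detected / n, 10) if n else np.nan,
            }
        )
    n_all = len(annotations)
    det_all = sum(verdicts[a.polyp_id].detected for a in annotations)
    rows.append(
        {
            "category": "overall",
            "label": "all",
            "n_polyps": n_all,
            "sensitivity_pct": round(100.0 * det_all / n_all, 10) if n_all else np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["category", "label", "n_polyps", "sensitivity_pct"])


def _study_curve(
    detection_times: Sequence[float], total_polyps: int, grid: np.ndarray
) -> np.ndarray:
    times = np.sort(np.asarray(detection_times, dtype=float))
    counts = np.searchsorted(times, grid, side="right")
    return counts / total_polyps


def sensitivity_time_curve(
    studies: Sequence[tuple[dict[str, DetectionVerdict], int]],
    t_max: float,
    grid_step_s: float = 1.0,
) -> SensitivityCurve:
    """Mean cumulative sensitivity over elapsed review time.

    Each study contributes a step curve that jumps 1/total at each lesion's
    first detection time; studies are averaged pointwise with equal weight
    on a common grid from 0 to ``t_max``. Studies with zero lesions are
    excluded with a warning (their sensitivity is undefined).
    """
    if t_max <= 0 or grid_step_s <= 0:
        raise ValidationError("t_max and grid_step_s must be > 0")
    grid = np.arange(0.0, t_max + grid_step_s / 2, grid_step_s)
    per_study = []
    for verdicts, total in studies:
        if total == 0:
            logger.warning("excluding study with zero lesions from the mean curve")
            continue
        times = [
            v.first_detection_time_s
            for v in verdicts.values()
            if v.detected and v.first_detection_time_s is not None
        ]
        per_study.append(_study_curve(times, total, grid))
    if not per_study:
        raise ValidationError("no study with lesions to average")
    mean = np.mean(per_study, axis=0)
    return SensitivityCurve(grid, mean)


def super_expert_curve(
    candidates: Sequence[CandidateSequence],
    annotations: Sequence[PolypAnnotation],
    seconds_per_candidate: float,
    t_max: float,
    grid_step_s: float = 1.0,
) -> SensitivityCurve:
    """Upper-bound curve for a given candidate order and pacing.

    Simulates a reader with p_recognize = 1 and p_false_call = 0 over the
    same display order; no stochastic reader with that order and pacing
    can exceed it at any time point.
    """
    params = ReaderParams(
        p_recognize=1.0,
        p_false_call=0.0,
        seconds_per_candidate=seconds_per_candidate,
        seed=0,
    )
    trace = simulate_reader(candidates, annotations, params, time_budget_s=math.inf)
    verdicts = match_detections(trace, annotations)
    return sensitivity_time_curve([(verdicts, len(annotations))], t_max, grid_step_s)


def time_to_parity(curve: SensitivityCurve, target: float) -> float:
    """Earliest time the curve reaches ``target`` sensitivity.

    Linearly interpolates between grid points; returns ``math.inf`` when
    the target is never reached.
    """
    if not (0.0 <= target <= 1.0):
        raise ValidationError(f"target sensitivity must lie in [0, 1], got {target}")
    t, s = curve.time_s, curve.sensitivity
    if s[0] >= target:
        return float(t[0])
    idx = np.argmax(s >= target)
    if s[idx] < target:
        return math.inf
    t0, t1 = t[idx - 1], t[idx]
    s0, s1 = s[idx - 1], s[idx]
    if s1 == s0:
        return float(t1)
    return float(t0 + (target - s0) / (s1 - s0) * (t1 - t0))


def speedup_factor(reference_time_s: float, parity_time_s: float) -> float:
    """How many times faster the triage arm reaches the reference arm's
    sensitivity: reference review time divided by time-to-parity."""
    if not math.isfinite(parity_time_s) or parity_time_s <= 0:
        raise TriageError(
            f"speed-up undefined for parity time {parity_time_s!r}"
        )
    if reference_time_s < 0:
        raise TriageError("reference time must be >= 0")
    return reference_time_s / parity_time_s


def sensitivity_gain(after_pct: float, before_pct: float) -> float:
    """Absolute sensitivity difference in percentage points."""
    return after_pct - before_pct
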