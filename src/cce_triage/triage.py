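"""Declining-certainty review order.

Turns scored frames into the display order a triage reviewer sees: frames
sorted by polyp probability (highest first), deduplicated by a temporal
suppression radius per head, and wrapped with k context frames on each
side of every accepted center.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from typing import Optional, Sequence

from .models import (
    HEADS,
    CandidateSequence,
    ConfigurationError,
    FrameRecord,
    ValidationError,
)

DEFAULT_CONTEXT_K = 4
DEFAULT_SUPPRESSION_RADIUS_S = 2.0


def rank_frames(frames: Sequence[FrameRecord]) -> list[FrameRecord]:
    """Sort frames by score descending — the "declining certainty" order.

    Ties break by timestamp ascending, then front head before rear, so the
    ordering is total and stable across runs.
    """
    for f in frames:
        if f.score is None:
            raise ValidationError(f"frame {f.frame_index} has no score")
    return sorted(
        frames,
        key=lambda f: (-f.score, f.timestamp_s, HEADS.index(f.head), f.frame_index),
    )


def build_candidates(
    ranked: Sequence[FrameRecord],
    k: int = DEFAULT_CONTEXT_K,
    suppression_radius_s: float = DEFAULT_SUPPRESSION_RADIUS_S,
    max_candidates: Optional[int] = None,
) -> list[CandidateSequence]:
    """Greedy temporal non-maximum suppression over the ranked frames.

    Walks the ranking from the top; a frame becomes a candidate center
    unless its timestamp lies within ``suppression_radius_s`` of an
    already-accepted center on the same head (closed comparison, so a
    radius of 0 only suppresses exact-coincident timestamps and in
    practice disables suppression). Context windows take the k immediately
    adjacent frame indices per side on the same head, truncated at video
    boundaries — nothing is padded or fabricated.
    """
    if k < 0:
        raise ConfigurationError("context radius k must be >= 0")
    if suppression_radius_s < 0:
        raise ConfigurationError("suppression_radius_s must be >= 0")
    if max_candidates is not None and max_candidates < 0:
        raise ConfigurationError("max_candidates must be >= 0")

    by_head: dict[tuple[str, str], dict[int, FrameRecord]] = {}
    for f in ranked:
        by_head.setdefault((f.study_id, f.head), {})[f.frame_index] = f

    accepted_times: dict[tuple[str, str], list[float]] = {}
    out: list[CandidateSequence] = []
    for f in ranked:
        if max_candidates is not None and len(out) >= max_candidates:
            break
        key = (f.study_id, f.head)
        times = accepted_times.setdefault(key, [])
        pos = bisect_left(times, f.timestamp_s)
        near = []
        if pos > 0:
            near.append(times[pos - 1])
        if pos < len(times):
            near.append(times[pos])
        if any(abs(f.timestamp_s - t) <= suppression_radius_s for t in near):
            continue
        insort(times, f.timestamp_s)
        index = by_head[key]
        before = tuple(
            index[j]
            for j in range(f.frame_index - k, f.frame_index)
            if j in index
        )
        after = tuple(
            index[j]
            for j in range(f.frame_index + 1, f.frame_index + k + 1)
            if j in index
        )
        out.append(
            CandidateSequence(
                rank=len(out) + 1,
                center=f,
                context_before=before,
                context_after=after,
            )
        )
    return out


DEFAULT_PALETTE: list[tuple[float, str]] = [
    (0.25, "blue"),
    (0.5, "teal"),
    (0.75, "orange"),
    (1.0, "vermillion"),
]


def assign_color_bin(
    score: float, palette: Sequence[tuple[float, str]] = DEFAULT_PALETTE
) -> str:
    """Map a probability to the label of the first bin whose upper
    threshold is >= score. The palette must have strictly increasing
    thresholds ending at 1.0 so all of [0, 1] is covered."""
    if not palette:
        raise ConfigurationError("palette must not be empty")
    thresholds = [t for t, _ in palette]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigurationError("palette thresholds must be strictly increasing")
    if thresholds[-1] != 1.0:
        raise ConfigurationError("palette must end at threshold 1.0")
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score must lie in [0, 1], got {score}")
    for threshold, label in palette:
        if score <= threshold:
            return label
    return palette[-1][1]


def load_palette_yaml(text: str) -> list[tuple[float, str]]:
    """Parse a palette from YAML: a list of {threshold, label} mappings."""
    import yaml

    raw = yaml.safe_load(text)
    try:
        palette = [(float(e["threshold"]), str(e["label"])) for e in raw]
    except (TypeError, KeyError):
        raise ConfigurationError(
            "palette YAML must be a list of {threshold, label} entries"
        )
    assign_color_bin(0.0, palette)  # validates structure
    return palette
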