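"""Readers and writers for the toolkit's tabular formats.

All tables are comma-separated UTF-8 with a mandatory header row and dot
decimals; timestamps are seconds from capsule start. Validation is total:
every malformed input raises a typed error naming the offending column or
row rather than being silently skipped.

Formats
-------
frame scores   ``study_id,head,frame_index,timestamp_s,score[,image_path]``
annotations    ``polyp_id,head,first_ts,last_ts,size_mm,morphology,n_visible_frames``
candidates     ``rank,study_id,head,center_frame_index,center_timestamp_s,
               display_score,context_before_indices,context_after_indices``
report dir     ``stratified.csv``, ``curve.csv``, ``summary.json``
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    CandidateSequence,
    FrameRecord,
    PolypAnnotation,
    SchemaError,
    SensitivityCurve,
    TriageError,
    ValidationError,
)

FRAME_COLUMNS = ["study_id", "head", "frame_index", "timestamp_s", "score"]
ANNOTATION_COLUMNS = [
    "polyp_id",
    "head",
    "first_ts",
    "last_ts",
    "size_mm",
    "morphology",
    "n_visible_frames",
]
CANDIDATE_COLUMNS = [
    "rank",
    "study_id",
    "head",
    "center_frame_index",
    "center_timestamp_s",
    "display_score",
    "context_before_indices",
    "context_after_indices",
]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TriageError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file has no header row")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _parse(value: str, kind: type, column: str, row: int):
    try:
        return kind(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column {column!r} has unparseable value {value!r}"
        )


def load_frame_scores(path: str | Path) -> list[FrameRecord]:
    """Load per-frame polyp probability scores, preserving file order.

    Raises :class:`SchemaError` for missing columns, :class:`ValidationError`
    (with the 1-based data row number) for out-of-range scores, bad heads,
    or timestamps that do not increase with frame index within a head.
    """
    df = _read_table(path, FRAME_COLUMNS)
    records: list[FrameRecord] = []
    has_image = "image_path" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = FrameRecord(
                study_id=row.study_id,
                head=row.head,
                frame_index=_parse(row.frame_index, int, "frame_index", i),
                timestamp_s=_parse(row.timestamp_s, float, "timestamp_s", i),
                score=_parse(row.score, float, "score", i),
                image_path=(getattr(row, "image_path") or None) if has_image else None,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    _check_monotone(records, path)
    return records


def _check_monotone(records: Iterable[FrameRecord], path) -> None:
    last: dict[tuple[str, str], FrameRecord] = {}
    for rec in sorted(records, key=lambda r: (r.study_id, r.head, r.frame_index)):
        key = (rec.study_id, rec.head)
        prev = last.get(key)
        if prev is not None:
            if rec.frame_index == prev.frame_index:
                raise ValidationError(
                    f"{path}: duplicate frame_index {rec.frame_index} "
                    f"on head {rec.head!r}"
                )
            if rec.timestamp_s <= prev.timestamp_s:
                raise ValidationError(
                    f"{path}: timestamps not strictly increasing with frame_index "
                    f"on head {rec.head!r} (frame {rec.frame_index})"
                )
        last[key] = rec


def write_frame_scores(records: Sequence[FrameRecord], path: str | Path) -> None:
    rows = [
        {
            "study_id": r.study_id,
            "head": r.head,
            "frame_index": r.frame_index,
            "timestamp_s": r.timestamp_s,
            "score": r.score,
            "image_path": r.image_path or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=FRAME_COLUMNS + ["image_path"]).to_csv(
        path, index=False
    )


def load_annotations(path: str | Path) -> list[PolypAnnotation]:
    """Load ground-truth lesion annotations (CSV or JSON list of objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        if not path.exists():
            raise TriageError(f"no such file: {path}")
        raw = json.loads(path.read_text())
        df = pd.DataFrame(raw, columns=ANNOTATION_COLUMNS if raw else None)
        if raw:
            missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
            if missing:
                raise SchemaError(f"{path}: missing field(s) {', '.join(missing)}")
        else:
            return []
        df = df.astype(str)
    else:
        df = _read_table(path, ANNOTATION_COLUMNS)
    annotations: list[PolypAnnotation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.polyp_id in seen:
            raise ValidationError(f"row {i}: duplicate polyp_id {row.polyp_id!r}")
        seen.add(row.polyp_id)
        try:
            ann = PolypAnnotation(
                polyp_id=row.polyp_id,
                head=row.head,
                first_ts=_parse(row.first_ts, float, "first_ts", i),
                last_ts=_parse(row.last_ts, float, "last_ts", i),
                size_mm=_parse(row.size_mm, float, "size_mm", i),
                morphology=row.morphology,
                n_visible_frames=_parse(
                    row.n_visible_frames, int, "n_visible_frames", i
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        annotations.append(ann)
    return annotations


def write_annotations(annotations: Sequence[PolypAnnotation], path: str | Path) -> None:
    rows = [
        {
            "polyp_id": a.polyp_id,
            "head": a.head,
            "first_ts": a.first_ts,
            "last_ts": a.last_ts,
            "size_mm": a.size_mm,
            "morphology": a.morphology,
            "n_visible_frames": a.n_visible_frames,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def _indices_to_str(frames: Sequence[FrameRecord]) -> str:
    return ";".join(str(f.frame_index) for f in frames)


def write_candidates(candidates: Sequence[CandidateSequence], path: str | Path) -> None:
    rows = [
        {
            "rank": c.rank,
            "study_id": c.center.study_id,
            "head": c.head,
            "center_frame_index": c.center.frame_index,
            "center_timestamp_s": c.center.timestamp_s,
            "display_score": c.display_score,
            "context_before_indices": _indices_to_str(c.context_before),
            "context_after_indices": _indices_to_str(c.context_after),
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, index=False)


def load_candidates(
    path: str | Path,
    frames: Optional[Sequence[FrameRecord]] = None,
) -> list[CandidateSequence]:
    """Load a ranked candidate table.

    When ``frames`` is given, context windows are rebuilt from the stored
    frame indices; otherwise candidates carry empty context (evaluation
    only needs the center frame).
    """
    df = _read_table(path, CANDIDATE_COLUMNS)
    lookup: dict[tuple[str, str, int], FrameRecord] = {}
    if frames is not None:
        lookup = {(f.study_id, f.head, f.frame_index): f for f in frames}

    def _ctx(study: str, head: str, spec: str) -> tuple[FrameRecord, ...]:
        if not spec or not lookup:
            return ()
        return tuple(lookup[(study, head, int(tok))] for tok in spec.split(";"))

    out: list[CandidateSequence] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        center = FrameRecord(
            study_id=row.study_id,
            head=row.head,
            frame_index=_parse(row.center_frame_index, int, "center_frame_index", i),
            timestamp_s=_parse(
                row.center_timestamp_s, float, "center_timestamp_s", i
            ),
            score=_parse(row.display_score, float, "display_score", i),
        )
        out.append(
            CandidateSequence(
                rank=_parse(row.rank, int, "rank", i),
                center=center,
                context_before=_ctx(row.study_id, row.head, row.context_before_indices),
                context_after=_ctx(row.study_id, row.head, row.context_after_indices),
            )
        )
    ranks = [c.rank for c in out]
    if ranks != list(range(1, len(ranks) + 1)):
        raise ValidationError(f"{path}: ranks must be consecutive from 1")
    return out


@dataclass
class ReportBundle:
    """Everything one evaluation run produces, ready to serialize."""

    stratified: pd.DataFrame  # columns: category,label,n_polyps,sensitivity_pct
    curves: dict[str, SensitivityCurve]
    summary: dict = field(default_factory=dict)


def write_report(bundle: ReportBundle, outdir: str | Path) -> dict[str, Path]:
    """Write ``stratified.csv``, ``curve.csv`` and ``summary.json``.

    All curves in the bundle must share a time grid; they are written as
    one table with a ``time_s`` column plus one column per curve. Floats
    round-trip through :func:`load_curves` to better than 1e-12.
    """
    outdir = Path(outdir)
    if not bundle.curves:
        raise ValidationError("report bundle has no curves")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stratified": outdir / "stratified.csv",
        "curve": outdir / "curve.csv",
        "summary": outdir / "summary.json",
    }
    bundle.stratified.to_csv(paths["stratified"], index=False)

    grids = [c.time_s for c in bundle.curves.values()]
    if not all(np.array_equal(grids[0], g) for g in grids[1:]):
        raise ValidationError("all report curves must share one time grid")
    table = {"time_s": grids[0]}
    for name, curve in bundle.curves.items():
        table[name] = curve.sensitivity
    pd.DataFrame(table).to_csv(paths["curve"], index=False)

    def _jsonable(v):
        if isinstance(v, float) and math.isinf(v):
            return "inf"
        return v

    paths["summary"].write_text(
        json.dumps({k: _jsonable(v) for k, v in bundle.summary.items()}, indent=2)
        + "\n"
    )
    return paths


def load_curves(path: str | Path) -> dict[str, SensitivityCurve]:
    df = _read_table(path, ["time_s"])
    df = df.astype(float)
    t = df["time_s"].to_numpy()
    return {
        name: SensitivityCurve(t, df[name].to_numpy())
        for name in df.columns
        if name != "time_s"
    }


def load_stratified(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ["category", "label", "n_polyps", "sensitivity_pct"])
    df["n_polyps"] = df["n_polyps"].astype(int)
    df["sensitivity_pct"] = pd.to_numeric(
        df["sensitivity_pct"].replace("", np.nan)
    )
    return df


def load_summary(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise TriageError(f"no such file: {path}")
    raw = json.loads(path.read_text())
    return {k: (math.inf if v == "inf" else v) for k, v in raw.items()}


def load_report(outdir: str | Path) -> ReportBundle:
    outdir = Path(outdir)
    return ReportBundle(
        stratified=load_stratified(outdir / "stratified.csv"),
        curves=load_curves(outdir / "curve.csv"),
        summary=load_summary(outdir / "summary.json"),
    )
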