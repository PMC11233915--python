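"""Reading, validation and writing of tracked-whisker tables.

The trace dialect is long-format delimited text with one row per whisker per
frame: ``clip_id, frame_index, side, whisker_id, angle_deg``.  Angles are in
head-centric degrees, 0 deg caudal along the head midline and increasing
rostrally, so larger angles mean more protracted whiskers.  Clip metadata
(one row per clip) carries the experimental design factors and the
pre-contact / during-contact split point.

Quality control encodes the machine-checkable clip-inclusion criteria:
minimum pre-contact (PC) and during-contact (DC) segment lengths, per-frame
whisker-count bounds, bilateral coverage, and a cap on clips per animal.
Head-level and travel-direction criteria are manual video selection done
upstream of tracking and are not re-checked here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TRACE_COLUMNS",
    "METADATA_COLUMNS",
    "METRIC_NAMES",
    "METRIC_COLUMNS",
    "SIDES",
    "TREATMENTS",
    "SEXES",
    "TEXTURES",
    "ClipMetadata",
    "QcConfig",
    "QcReport",
    "SchemaError",
    "TraceValidationError",
    "read_traces",
    "read_metadata",
    "write_traces",
    "write_metadata",
    "qc_clip",
    "qc_cohort",
    "write_qc_report",
    "write_metrics_table",
    "read_metrics_table",
]

TRACE_COLUMNS = ["clip_id", "frame_index", "side", "whisker_id", "angle_deg"]
METADATA_COLUMNS = [
    "clip_id",
    "animal_id",
    "treatment",
    "sex",
    "object_texture",
    "contact_frame",
    "frame_rate",
    "n_frames",
]

SIDES = ("left", "right")
TREATMENTS = ("MIA", "control")
SEXES = ("male", "female")
TEXTURES = ("smooth", "textured")

#: The six whisker metrics, in their canonical reporting order.
METRIC_NAMES = [
    "mean_angle",
    "amplitude",
    "asymmetry",
    "spread",
    "protraction_speed",
    "retraction_speed",
]

#: Tidy metrics-table columns: six metrics for each of PC, DC and the
#: contact-related change delta = PC - DC.
METRIC_COLUMNS = (
    [f"pc_{m}" for m in METRIC_NAMES]
    + [f"dc_{m}" for m in METRIC_NAMES]
    + [f"delta_{m}" for m in METRIC_NAMES]
)


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class TraceValidationError(ValueError):
    """A row-level value violates the trace or metadata contract."""


@dataclass(frozen=True)
class ClipMetadata:
    """Design factors and segmentation for one filmed clip.

    ``contact_frame`` is the first during-contact frame (0-based): PC is the
    half-open frame range ``[0, contact_frame)`` and DC is
    ``[contact_frame, n_frames)``.
    """

    clip_id: str
    animal_id: str
    treatment: str
    sex: str
    object_texture: str
    contact_frame: int
    frame_rate: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise TraceValidationError(
                f"clip {self.clip_id}: treatment {self.treatment!r} not in {TREATMENTS}"
            )
        if self.sex not in SEXES:
            raise TraceValidationError(
                f"clip {self.clip_id}: sex {self.sex!r} not in {SEXES}"
            )
        if self.object_texture not in TEXTURES:
            raise TraceValidationError(
                f"clip {self.clip_id}: object_texture {self.object_texture!r} "
                f"not in {TEXTURES}"
            )
        if self.frame_rate <= 0:
            raise TraceValidationError(
                f"clip {self.clip_id}: frame_rate must be > 0, got {self.frame_rate}"
            )
        if not (0 < self.contact_frame < self.n_frames):
            raise TraceValidationError(
                f"clip {self.clip_id}: contact_frame {self.contact_frame} must lie "
                f"strictly inside (0, n_frames={self.n_frames})"
            )


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for clip-level quality control (all configurable)."""

    min_pc_frames: int = 100
    min_dc_frames: int = 100
    min_whiskers_per_frame: int = 2
    max_whiskers_per_frame: int = 12
    min_bilateral_fraction: float = 0.9
    max_clips_per_animal: int = 4


@dataclass
class QcReport:
    """Pass/fail record for one clip; ``passed`` iff ``reasons`` is empty."""

    clip_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_traces(path: str | Path, *, sep: str = ",") -> pd.DataFrame:
    """Read and validate a long-format whisker-trace table.

    Returns a DataFrame with columns :data:`TRACE_COLUMNS`, sorted by
    ``(clip_id, frame_index, side, whisker_id)``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    TraceValidationError
        On non-finite/out-of-range angles, unknown sides, negative frame
        indices or duplicate (clip, frame, side, whisker) keys.  Messages
        carry 1-based data-row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={"clip_id": str, "whisker_id": str, "side": str})
    _require_columns(df, TRACE_COLUMNS, f"trace table {path.name}")
    df = df[TRACE_COLUMNS].copy()

    angles = pd.to_numeric(df["angle_deg"], errors="coerce").to_numpy(float)
    bad = ~np.isfinite(angles)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise TraceValidationError(
            f"{path.name}: non-numeric or non-finite angle at data row {row}"
        )
    out_of_range = (angles < 0.0) | (angles > 180.0)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0]) + 1
        raise TraceValidationError(
            f"{path.name}: angle outside [0, 180] degrees at data row {row} "
            f"(got {angles[out_of_range][0]:g})"
        )
    df["angle_deg"] = angles

    unknown_side = ~df["side"].isin(SIDES)
    if unknown_side.any():
        row = int(np.flatnonzero(unknown_side.to_numpy())[0]) + 1
        raise TraceValidationError(
            f"{path.name}: side must be one of {SIDES}, bad value at data row {row}"
        )
    frames = pd.to_numeric(df["frame_index"], errors="coerce")
    if frames.isna().any() or (frames < 0).any() or (frames != frames.astype(int)).any():
        raise TraceValidationError(f"{path.name}: frame_index must be integer >= 0")
    df["frame_index"] = frames.astype(np.int64)

    dup = df.duplicated(subset=["clip_id", "frame_index", "side", "whisker_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise TraceValidationError(
            f"{path.name}: duplicate (clip_id, frame_index, side, whisker_id) "
            f"at data row {row}"
        )
    return df.sort_values(
        ["clip_id", "frame_index", "side", "whisker_id"], kind="mergesort"
    ).reset_index(drop=True)


def write_traces(df: pd.DataFrame, path: str | Path, *, overwrite: bool = False) -> Path:
    """Write a trace table in the canonical dialect (CSV, sorted, 6 d.p.)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    _require_columns(df, TRACE_COLUMNS, "trace table")
    out = df[TRACE_COLUMNS].sort_values(
        ["clip_id", "frame_index", "side", "whisker_id"], kind="mergesort"
    )
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_metadata(path: str | Path, *, sep: str = ",") -> dict[str, ClipMetadata]:
    """Read clip metadata; returns a mapping clip_id -> :class:`ClipMetadata`.

    Factor levels are validated against the allowed sets and clip ids must
    be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={"clip_id": str, "animal_id": str})
    _require_columns(df, METADATA_COLUMNS, f"metadata table {path.name}")
    if df["clip_id"].duplicated().any():
        dupes = df.loc[df["clip_id"].duplicated(), "clip_id"].tolist()
        raise TraceValidationError(f"{path.name}: duplicate clip_id(s): {dupes}")
    records: dict[str, ClipMetadata] = {}
    for _, row in df.iterrows():
        meta = ClipMetadata(
            clip_id=str(row["clip_id"]),
            animal_id=str(row["animal_id"]),
            treatment=str(row["treatment"]),
            sex=str(row["sex"]),
            object_texture=str(row["object_texture"]),
            contact_frame=int(row["contact_frame"]),
            frame_rate=float(row["frame_rate"]),
            n_frames=int(row["n_frames"]),
        )
        records[meta.clip_id] = meta
    return records


def write_metadata(
    metadata: Iterable[ClipMetadata], path: str | Path, *, overwrite: bool = False
) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    rows = [
        {
            "clip_id": m.clip_id,
            "animal_id": m.animal_id,
            "treatment": m.treatment,
            "sex": m.sex,
            "object_texture": m.object_texture,
            "contact_frame": m.contact_frame,
            "frame_rate": m.frame_rate,
            "n_frames": m.n_frames,
        }
        for m in metadata
    ]
    if not rows:
        raise ValueError("refusing to write an empty metadata table")
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)
    return path


def qc_clip(
    clip_traces: pd.DataFrame,
    meta: ClipMetadata,
    config: QcConfig | None = None,
) -> QcReport:
    """Apply the clip-inclusion criteria to one tracked clip.

    Failures are reported, never raised.  Codes: ``short-PC``, ``short-DC``,
    ``whisker-count-out-of-range``, ``missing-side``.  The per-animal clip
    cap is a cohort-level criterion and is applied by :func:`qc_cohort`
    (code ``excess-clips-per-animal``).
    """
    config = config or QcConfig()
    reasons: list[str] = []

    pc_len = meta.contact_frame
    dc_len = meta.n_frames - meta.contact_frame
    if pc_len < config.min_pc_frames:
        reasons.append("short-PC")
    if dc_len < config.min_dc_frames:
        reasons.append("short-DC")

    counts = clip_traces.groupby("frame_index").size()
    if len(counts) and (
        (counts < config.min_whiskers_per_frame).any()
        or (counts > config.max_whiskers_per_frame).any()
    ):
        reasons.append("whisker-count-out-of-range")

    n_frames_observed = clip_traces["frame_index"].nunique()
    if n_frames_observed == 0:
        reasons.append("missing-side")
    else:
        bilateral = clip_traces.groupby("frame_index")["side"].nunique()
        frac_bilateral = float((bilateral == 2).sum()) / n_frames_observed
        if frac_bilateral < config.min_bilateral_fraction:
            reasons.append("missing-side")

    return QcReport(clip_id=meta.clip_id, passed=not reasons, reasons=reasons)


def qc_cohort(
    traces: pd.DataFrame,
    metadata: dict[str, ClipMetadata],
    config: QcConfig | None = None,
) -> list[QcReport]:
    """QC every clip, then enforce the per-animal clip cap.

    When an animal has more than ``max_clips_per_animal`` otherwise-passing
    clips, the surplus (by clip_id order, deterministic) is failed with code
    ``excess-clips-per-animal``.
    """
    config = config or QcConfig()
    grouped = dict(tuple(traces.groupby("clip_id"))) if len(traces) else {}
    reports: list[QcReport] = []
    for clip_id in sorted(metadata):
        clip_df = grouped.get(clip_id, traces.iloc[0:0])
        reports.append(qc_clip(clip_df, metadata[clip_id], config))

    by_animal: dict[str, list[QcReport]] = {}
    for rep in reports:
        if rep.passed:
            by_animal.setdefault(metadata[rep.clip_id].animal_id, []).append(rep)
    for animal_reports in by_animal.values():
        for rep in animal_reports[config.max_clips_per_animal :]:
            rep.passed = False
            rep.reasons.append("excess-clips-per-animal")
    return reports


def write_qc_report(reports: Iterable[QcReport], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"clip_id": r.clip_id, "passed": r.passed, "reasons": ";".join(r.reasons)}
        for r in reports
    ]
    pd.DataFrame(rows, columns=["clip_id", "passed", "reasons"]).to_csv(path, index=False)
    return path


def write_metrics_table(
    rows: pd.DataFrame, path: str | Path, *, overwrite: bool = False
) -> Path:
    """Write the tidy per-clip metrics table (metadata factors + 18 metrics).

    Column order is stable: metadata first, then PC, DC and delta blocks.
    Values are written at 9 significant-digit precision, which round-trips
    the analysis losslessly at the reported precision.
    """
    if len(rows) == 0:
        raise ValueError("refusing to write an empty metrics table")
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    cols = METADATA_COLUMNS + [c for c in METRIC_COLUMNS if c in rows.columns]
    _require_columns(rows, cols, "metrics table")
    rows[cols].to_csv(path, index=False, float_format="%.9g")
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"clip_id": str, "animal_id": str})
    _require_columns(df, METADATA_COLUMNS, f"metrics table {path.name}")
    return df
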