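"""Whisker-movement metrics from tracked angle time series.

A clip is reduced in two steps.  First, whiskers are aggregated within each
frame and side into a :class:`SideAngleSeries` (per-frame mean angle,
across-whisker SD, whisker count); no whisker identity across frames is
required, which keeps the pipeline robust to whiskers appearing and
disappearing between frames.  Second, the pre-contact (PC) and
during-contact (DC) segments of the per-side series are summarised into six
metrics:

- ``mean_angle``: time average of the per-side mean angle, averaged across
  sides (degrees; higher = whiskers held more forward).
- ``amplitude``: 2*sqrt(2) times the SD of the per-side mean-angle series,
  averaged across sides (degrees; equals peak-to-peak for a sinusoid).
- ``asymmetry``: |mean over frames of (left - right mean angle)| (degrees);
  the signed value is kept as an auxiliary output.
- ``spread``: mean over frames and sides of the across-whisker SD (degrees;
  low spread = bunched whiskers).
- ``protraction_speed`` / ``retraction_speed``: mean |angular velocity| over
  frames where the smoothed mean angle is increasing / decreasing
  (degrees/second), per side then averaged across sides.

Contact-related change is reported as delta = PC - DC for every metric, so
a positive delta means the quantity *decreased* on contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .trace_io import METRIC_NAMES, SIDES, ClipMetadata

__all__ = [
    "KinematicsConfig",
    "SideAngleSeries",
    "SegmentMetrics",
    "ClipMetrics",
    "EmptySegmentError",
    "per_side_series",
    "side_series_from_array",
    "smooth_series",
    "angular_velocity",
    "mean_angular_position",
    "whisker_amplitude",
    "whisker_asymmetry",
    "whisker_spread",
    "movement_speeds",
    "segment_metrics",
    "compute_clip_metrics",
    "metrics_table",
]

_SQRT8 = 2.0 * math.sqrt(2.0)


class EmptySegmentError(ValueError):
    """A requested segment contains no frames or no usable data."""


@lru_cache(maxsize=64)
def _center_weights(half_width: int, order: int) -> np.ndarray:
    """Centre-point weights of a symmetric local polynomial fit.

    Used for the shrunk edge windows; half_width 0 returns the identity
    weight (the end samples pass through unchanged).
    """
    from scipy.signal import savgol_coeffs

    if half_width == 0:
        return np.ones(1)
    m = 2 * half_width + 1
    return savgol_coeffs(m, min(order, m - 1), use="dot")


@dataclass(frozen=True)
class KinematicsConfig:
    """Options for metric computation.

    smoothing_window/order: local polynomial (Savitzky-Golay) smoothing
    applied to the per-side mean-angle series before differentiation; the
    published convention is a 2nd-order fit over 15 neighbouring samples.
    Positional metrics (mean angle, amplitude, asymmetry, spread) are
    computed on the raw series; set ``smooth_positions=True`` to smooth
    those too.  ``signed_asymmetry`` switches the reported asymmetry from
    |left - right| to the signed left - right mean.
    """

    smoothing_window: int = 15
    smoothing_order: int = 2
    smooth_positions: bool = False
    signed_asymmetry: bool = False


@dataclass
class SideAngleSeries:
    """Per-frame aggregate of all tracked whiskers on one side.

    ``mean_angle`` and ``sd`` are frame-indexed arrays; frames where the
    side was not tracked are NaN, and ``sd`` is NaN wherever fewer than two
    whiskers were seen (a sample SD needs n >= 2).
    """

    side: str
    mean_angle: np.ndarray
    sd: np.ndarray
    count: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        n = len(self.mean_angle)
        if len(self.sd) != n or len(self.count) != n:
            raise ValueError("mean_angle, sd and count must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return len(self.mean_angle)

    def slice(self, start: int, stop: int) -> "SideAngleSeries":
        return SideAngleSeries(
            side=self.side,
            mean_angle=self.mean_angle[start:stop],
            sd=self.sd[start:stop],
            count=self.count[start:stop],
            frame_rate=self.frame_rate,
        )


@dataclass
class SegmentMetrics:
    """The six whisker metrics for one clip segment (PC or DC).

    Speeds are NaN when the segment has no frame moving in that direction;
    ``asymmetry_signed`` (left - right) is an auxiliary output for callers
    who know the contact side.  ``single_side`` flags metrics computed from
    one side only.
    """

    segment: str
    mean_angle: float
    amplitude: float
    asymmetry: float
    asymmetry_signed: float
    spread: float
    protraction_speed: float
    retraction_speed: float
    single_side: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class ClipMetrics:
    """Per-clip PC and DC metrics plus contact-related deltas (PC - DC)."""

    meta: ClipMetadata
    pc: SegmentMetrics
    dc: SegmentMetrics

    @property
    def delta(self) -> dict[str, float]:
        pc, dc = self.pc.as_dict(), self.dc.as_dict()
        return {name: pc[name] - dc[name] for name in METRIC_NAMES}

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "clip_id": self.meta.clip_id,
            "animal_id": self.meta.animal_id,
            "treatment": self.meta.treatment,
            "sex": self.meta.sex,
            "object_texture": self.meta.object_texture,
            "contact_frame": self.meta.contact_frame,
            "frame_rate": self.meta.frame_rate,
            "n_frames": self.meta.n_frames,
        }
        for label, seg in (("pc", self.pc.as_dict()), ("dc", self.dc.as_dict())):
            for name in METRIC_NAMES:
                row[f"{label}_{name}"] = seg[name]
        for name, value in self.delta.items():
            row[f"delta_{name}"] = value
        return row


def per_side_series(
    clip_traces: pd.DataFrame, meta: ClipMetadata
) -> dict[str, SideAngleSeries]:
    """Aggregate a long-format clip into one :class:`SideAngleSeries` per side.

    Frames are indexed 0..n_frames-1; frames with no tracked whisker on a
    side are NaN for that side.
    """
    n = meta.n_frames
    out: dict[str, SideAngleSeries] = {}
    for side in SIDES:
        sub = clip_traces[clip_traces["side"] == side]
        frames = sub["frame_index"].to_numpy(np.int64)
        angles = sub["angle_deg"].to_numpy(float)
        if frames.size and (frames.min() < 0 or frames.max() >= n):
            raise ValueError(
                f"clip {meta.clip_id}: frame_index outside [0, {n}) on side {side}"
            )
        count = np.bincount(frames, minlength=n).astype(np.int64)
        sums = np.bincount(frames, weights=angles, minlength=n)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(count > 0, sums / np.maximum(count, 1), np.nan)
            sq = np.bincount(frames, weights=angles**2, minlength=n)
            # sample variance via sum of squares; guarded against tiny
            # negative round-off
            var = np.where(
                count >= 2,
                np.maximum(sq - count * mean**2, 0.0) / np.maximum(count - 1, 1),
                np.nan,
            )
        out[side] = SideAngleSeries(
            side=side,
            mean_angle=mean,
            sd=np.sqrt(var),
            count=count,
            frame_rate=meta.frame_rate,
        )
    return out


def side_series_from_array(
    angles: np.ndarray, side: str, frame_rate: float
) -> SideAngleSeries:
    """Build a per-side series from a dense (n_frames, n_whiskers) array.

    NaN entries mark whiskers missing in a frame.  This is the fast path
    used by the simulator; it is numerically identical to aggregating the
    equivalent long-format table.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2:
        raise ValueError("angles must be 2-D (frames x whiskers)")
    count = np.sum(np.isfinite(angles), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nanmean(angles, axis=1), np.nan)
        sd = np.full(len(angles), np.nan)
        ok = count >= 2
        if ok.any():
            sd[ok] = np.nanstd(angles[ok], axis=1, ddof=1)
    return SideAngleSeries(
        side=side, mean_angle=mean, sd=sd, count=count, frame_rate=frame_rate
    )


def smooth_series(
    series: np.ndarray, window: int = 15, order: int = 2
) -> np.ndarray:
    """Local least-squares polynomial (Savitzky-Golay) smoothing.

    Interior points use the full centred window; near each edge the window
    shrinks symmetrically (at index i, half-width min(h, i, n-1-i)), with
    the polynomial degree capped by the shrunk window size, so the first
    and last samples are returned unchanged.  Output length equals input
    length; an exact polynomial of the fitted order is reproduced to
    numerical tolerance.  NaN runs (untracked frames) are preserved: each
    window fit uses only finite samples.
    """
    from scipy.signal import savgol_filter

    x = np.asarray(series, dtype=float)
    n = len(x)
    if window % 2 != 1:
        raise ValueError("smoothing window must be odd")
    if window <= order:
        raise ValueError("smoothing window must exceed the polynomial order")
    if n < window:
        raise ValueError(
            f"series of length {n} is shorter than the smoothing window "
            f"{window}; lower the window"
        )
    h = window // 2
    has_nan = bool(np.isnan(x).any())
    out = np.empty_like(x)
    if not has_nan:
        # interior only; the shrunk-window edges below overwrite the rest
        out[:] = savgol_filter(x, window, order, mode="constant")
        for i in range(h):
            hw = i
            out[i] = _center_weights(hw, order) @ x[: 2 * hw + 1]
            out[n - 1 - i] = _center_weights(hw, order) @ x[n - 2 * hw - 1 :]
        return out
    for i in range(n):
        hw = min(h, i, n - 1 - i)
        lo, hi = i - hw, i + hw + 1
        win = x[lo:hi]
        t = np.arange(lo, hi, dtype=float) - i
        good = np.isfinite(win)
        if not np.isfinite(x[i]) or good.sum() == 0:
            out[i] = np.nan
            continue
        deg = min(order, int(good.sum()) - 1)
        if deg <= 0:
            out[i] = np.nanmean(win)
        else:
            coef = np.polynomial.polynomial.polyfit(t[good], win[good], deg)
            out[i] = coef[0]
    return out


def angular_velocity(series: np.ndarray, frame_rate: float) -> np.ndarray:
    """Per-frame angular velocity in degrees/second.

    Central differences in the interior, one-sided at the two edges.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("velocity needs at least 2 frames")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    return np.gradient(x) * frame_rate


def _valid_sides(left: SideAngleSeries, right: SideAngleSeries) -> list[SideAngleSeries]:
    sides = []
    for s in (left, right):
        if np.isfinite(s.mean_angle).any():
            sides.append(s)
    return sides


def mean_angular_position(
    left: SideAngleSeries, right: SideAngleSeries
) -> tuple[float, bool]:
    """Time-averaged mean whisker angle, averaged over the two sides.

    Returns (value, single_side); ``single_side`` is True when one side had
    no tracked frames and the value comes from the other side alone.
    """
    sides = _valid_sides(left, right)
    if not sides:
        raise EmptySegmentError("no side has any tracked frame")
    vals = [float(np.nanmean(s.mean_angle)) for s in sides]
    return float(np.mean(vals)), len(sides) < 2


def whisker_amplitude(left: SideAngleSeries, right: SideAngleSeries) -> float:
    """2*sqrt(2) x SD of the per-side mean-angle series, averaged over sides.

    For a pure sinusoid this recovers the peak-to-peak excursion.
    """
    sides = _valid_sides(left, right)
    if not sides:
        raise EmptySegmentError("no side has any tracked frame")
    vals = []
    for s in sides:
        good = s.mean_angle[np.isfinite(s.mean_angle)]
        if len(good) < 2:
            raise EmptySegmentError(
                f"side {s.side}: amplitude needs >= 2 tracked frames"
            )
        vals.append(_SQRT8 * float(np.std(good, ddof=1)))
    return float(np.mean(vals))


def whisker_asymmetry(
    left: SideAngleSeries, right: SideAngleSeries
) -> tuple[float, float]:
    """Left-right difference of mean whisker angle.

    Frames missing either side are excluded pairwise.  Returns
    (unsigned, signed) where signed = mean over frames of (left - right)
    and unsigned = |signed|.
    """
    d = left.mean_angle - right.mean_angle
    good = np.isfinite(d)
    if not good.any():
        raise EmptySegmentError("no frame has both sides tracked")
    signed = float(np.mean(d[good]))
    return abs(signed), signed


def whisker_spread(left: SideAngleSeries, right: SideAngleSeries) -> float:
    """Mean across-whisker SD over all frames and sides with a defined SD."""
    sds = np.concatenate([left.sd, right.sd])
    good = np.isfinite(sds)
    if not good.any():
        raise EmptySegmentError("no frame has >= 2 whiskers on either side")
    return float(np.mean(sds[good]))


def movement_speeds(
    left: SideAngleSeries,
    right: SideAngleSeries,
    config: KinematicsConfig | None = None,
) -> tuple[float, float]:
    """Mean protraction and retraction speeds in degrees/second.

    The per-side mean-angle series is smoothed (local polynomial fit, see
    :class:`KinematicsConfig`) and differentiated; frames with positive
    velocity (angle increasing = forward) contribute to protraction, frames
    with negative velocity to retraction, exact zeros to neither.  Per-side
    means are averaged over sides; a direction absent from every side is
    NaN, not zero.
    """
    config = config or KinematicsConfig()
    sides = _valid_sides(left, right)
    if not sides:
        raise EmptySegmentError("no side has any tracked frame")
    pro: list[float] = []
    ret: list[float] = []
    for s in sides:
        if len(s) < 3:
            raise EmptySegmentError("speeds need >= 3 frames")
        window = config.smoothing_window
        if len(s) < window:  # short segment: shrink to largest odd window
            window = max(config.smoothing_order + 1, len(s))
            window = window if window % 2 == 1 else window - 1
        smoothed = smooth_series(s.mean_angle, window, config.smoothing_order)
        v = angular_velocity(smoothed, s.frame_rate)
        v = v[np.isfinite(v)]
        # velocities at float round-off scale count as "not moving"
        tol = 1e-10 * s.frame_rate * max(1.0, float(np.nanmax(np.abs(smoothed))))
        if (v > tol).any():
            pro.append(float(np.mean(v[v > tol])))
        if (v < -tol).any():
            ret.append(float(np.mean(-v[v < -tol])))
    return (
        float(np.mean(pro)) if pro else float("nan"),
        float(np.mean(ret)) if ret else float("nan"),
    )


def segment_metrics(
    left: SideAngleSeries,
    right: SideAngleSeries,
    segment: str,
    config: KinematicsConfig | None = None,
) -> SegmentMetrics:
    """All six metrics for one segment from its two per-side series."""
    config = config or KinematicsConfig()
    if len(left) == 0 or len(right) == 0:
        raise EmptySegmentError(f"{segment} segment has zero frames")
    if config.smooth_positions:
        pos_left, pos_right = [], []
        for s in (left, right):
            sm = smooth_series(
                s.mean_angle, config.smoothing_window, config.smoothing_order
            )
            smoothed = SideAngleSeries(s.side, sm, s.sd, s.count, s.frame_rate)
            (pos_left if s is left else pos_right).append(smoothed)
        left_pos, right_pos = pos_left[0], pos_right[0]
    else:
        left_pos, right_pos = left, right
    mean_angle, single_side = mean_angular_position(left_pos, right_pos)
    amplitude = whisker_amplitude(left_pos, right_pos)
    if single_side:
        unsigned, signed = float("nan"), float("nan")
    else:
        unsigned, signed = whisker_asymmetry(left_pos, right_pos)
    spread = whisker_spread(left, right)
    pro, ret = movement_speeds(left, right, config)
    return SegmentMetrics(
        segment=segment,
        mean_angle=mean_angle,
        amplitude=amplitude,
        asymmetry=signed if config.signed_asymmetry else unsigned,
        asymmetry_signed=signed,
        spread=spread,
        protraction_speed=pro,
        retraction_speed=ret,
        single_side=single_side,
    )


def compute_clip_metrics(
    clip_traces: pd.DataFrame,
    meta: ClipMetadata,
    config: KinematicsConfig | None = None,
) -> ClipMetrics:
    """PC, DC and delta (PC - DC) metrics for one QC-passed clip.

    PC covers frames [0, contact_frame) and DC covers
    [contact_frame, n_frames); every frame belongs to exactly one segment.
    """
    series = per_side_series(clip_traces, meta)
    return clip_metrics_from_series(series["left"], series["right"], meta, config)


def clip_metrics_from_series(
    left: SideAngleSeries,
    right: SideAngleSeries,
    meta: ClipMetadata,
    config: KinematicsConfig | None = None,
) -> ClipMetrics:
    """As :func:`compute_clip_metrics`, starting from per-side series."""
    config = config or KinematicsConfig()
    cf, n = meta.contact_frame, meta.n_frames
    try:
        pc = segment_metrics(left.slice(0, cf), right.slice(0, cf), "PC", config)
        dc = segment_metrics(left.slice(cf, n), right.slice(cf, n), "DC", config)
    except (EmptySegmentError, ValueError) as err:
        raise type(err)(f"clip {meta.clip_id}: {err}") from err
    return ClipMetrics(meta=meta, pc=pc, dc=dc)


def metrics_table(
    traces: pd.DataFrame,
    metadata: dict[str, ClipMetadata],
    clip_ids: list[str] | None = None,
    config: KinematicsConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-clip metrics table for a set of clips (default: all)."""
    config = config or KinematicsConfig()
    if clip_ids is None:
        clip_ids = sorted(metadata)
    grouped = dict(tuple(traces.groupby("clip_id")))
    rows = []
    for clip_id in clip_ids:
        if clip_id not in grouped:
            raise KeyError(f"clip {clip_id} has no trace rows")
        rows.append(
            compute_clip_metrics(grouped[clip_id], metadata[clip_id], config).as_row()
        )
    return pd.DataFrame(rows)
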