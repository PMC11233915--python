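"""Synthetic whisking cohorts with injectable contact effects.

The generator emits tracked-angle tables with the statistical structure the
analysis pipeline assumes, so every stage can be exercised without animal
data.  Whisking is modelled as a single-frequency sinusoid rather than a
biomechanical simulation — the choice makes the ground truth analytic: the
peak-to-peak excursion, contact-related mean shift and asymmetry offset are
exact generative parameters that the kinematics metrics should recover.

For whisker w on side s of one clip the angle at frame time t is

    angle(t) = mu + u_animal + shift(t) + o_w(t)
               + (A(t)/2) sin(2*pi*f(t)*t + phi_s) + eps(t)

with u_animal an animal-level random intercept, o_w a per-whisker angular
offset (its SD is the spread driver), and eps white measurement noise.
Object contact (the during-contact segment) modulates the parameters:
amplitude A scales up, the whisker offsets scale down (whiskers bunch),
the whisking frequency scales down (slower movement), the two sides are
pushed apart by an asymmetry offset, and the mean angle gains a protraction
shift.  The contact mean shift varies at the animal level (a stable
per-animal contact response) and at the clip level, which gives the
clip-level metrics a genuine animal random-intercept / residual variance
decomposition.  Cell-specific effect injections override the contact
modulation for a named treatment x sex x texture cell, mimicking e.g. a
group that fails to protract on contact.

Randomness is disciplined: one root seed, with per-animal and per-clip
substreams spawned deterministically, so cohorts are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import kinematics
from .trace_io import SEXES, TRACE_COLUMNS, TREATMENTS, ClipMetadata

__all__ = [
    "DcModulation",
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "generate_clip",
    "generate_cohort",
    "inject_effect",
    "simulate_metrics_table",
    "cell_label",
]

Cell = tuple[str, str, str]  # (treatment, sex, texture)


def cell_label(treatment: str, sex: str, texture: str) -> str:
    return f"{treatment}:{sex}:{texture}"


@dataclass(frozen=True)
class DcModulation:
    """How object contact modulates the whisking parameters.

    amplitude_scale > 1 enlarges the whisk envelope during contact;
    spread_scale < 1 bunches the whiskers; speed_scale < 1 slows whisking
    (implemented as a frequency scale so amplitude ground truth stays
    clean); asymmetry_offset (degrees) pushes left up and right down by
    half each; mean_shift (degrees) is the contact protraction increase.
    """

    amplitude_scale: float = 1.25
    spread_scale: float = 0.6
    speed_scale: float = 0.6
    asymmetry_offset: float = 6.0
    mean_shift: float = 5.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a whisking cohort.

    Defaults emulate the cohort scale of a typical rat maternal-immune-
    activation study (about 50 animals in four treatment x sex cells, 1-4
    clips each, pre-contact segments of 100-291 frames and during-contact
    segments of 100-459 frames, 5-6 tracked whiskers per side) with an
    8 Hz whisk filmed at 500 frames/s.
    """

    animals_per_cell: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("MIA", "female"): 11,
            ("MIA", "male"): 13,
            ("control", "female"): 14,
            ("control", "male"): 12,
        }
    )
    clips_per_animal: tuple[int, int] = (1, 4)
    pc_frames: tuple[int, int] = (100, 291)
    dc_frames: tuple[int, int] = (100, 459)
    frame_rate: float = 500.0
    whiskers_per_side: tuple[int, int] = (5, 6)
    whisking_frequency: float = 8.0
    baseline_mean_angle: float = 100.0
    baseline_peak_to_peak: float = 40.0
    whisker_offset_sd: float = 5.0
    noise_sd: float = 2.0
    animal_intercept_sd: float = 3.0
    animal_contact_shift_sd: float = 3.0
    clip_contact_shift_sd: float = 2.0
    side_phase_offset: float = 0.0
    dropout_prob: float = 0.0
    dc: DcModulation = field(default_factory=DcModulation)
    effects: Mapping[Cell, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (*self.clips_per_animal, "clips_per_animal"),
            (*self.pc_frames, "pc_frames"),
            (*self.dc_frames, "dc_frames"),
            (*self.whiskers_per_side, "whiskers_per_side"),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.whisking_frequency >= self.frame_rate / 2:
            raise ValueError("whisking frequency must be below the Nyquist rate")
        if self.dc.amplitude_scale <= 0 or self.dc.spread_scale <= 0:
            raise ValueError("DC scales must be > 0")
        if self.dc.speed_scale <= 0:
            raise ValueError("DC speed scale must be > 0")
        for cell in self.effects:
            _validate_cell(cell)
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must be in [0, 1)")

    def dc_for_cell(self, cell: Cell) -> DcModulation:
        """Effective contact modulation for a treatment x sex x texture cell."""
        override = self.effects.get(tuple(cell))
        if not override:
            return self.dc
        return replace(self.dc, **dict(override))


def _validate_cell(cell: Cell) -> None:
    treatment, sex, texture = cell
    if treatment not in TREATMENTS or sex not in SEXES or texture not in (
        "smooth",
        "textured",
    ):
        raise ValueError(f"unknown treatment x sex x texture cell: {cell}")


def inject_effect(
    config: SyntheticConfig, cell: Cell, modulation: Mapping[str, float]
) -> SyntheticConfig:
    """Return a config whose contact modulation is overridden in one cell.

    ``modulation`` maps :class:`DcModulation` field names to replacement
    values; an empty mapping returns the config unchanged.  E.g.
    ``inject_effect(cfg, ("MIA", "female", "smooth"),
    {"mean_shift": 0.0, "asymmetry_offset": 0.0})`` cancels the contact
    protraction increase and contact-induced asymmetry in that cell only.
    """
    _validate_cell(cell)
    unknown = set(modulation) - set(DcModulation.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown DcModulation field(s): {sorted(unknown)}")
    if not modulation:
        return config
    effects = {tuple(k): dict(v) for k, v in config.effects.items()}
    effects.setdefault(tuple(cell), {}).update(modulation)
    return replace(config, effects=effects)


@dataclass
class GroundTruth:
    """Realized generative parameters for one emitted clip."""

    clip_id: str
    animal_id: str
    treatment: str
    sex: str
    object_texture: str
    pc_frames: int
    dc_frames: int
    animal_intercept: float
    animal_contact_shift: float
    mean_shift_realized: float
    pc_peak_to_peak: float
    dc_peak_to_peak: float
    asymmetry_offset: float
    pc_offset_scale: float
    dc_offset_scale: float
    pc_frequency: float
    dc_frequency: float
    phase: float

    def as_row(self) -> dict[str, object]:
        return dict(self.__dict__)


@dataclass
class AnimalState:
    """Per-animal latent draws shared by all of the animal's clips."""

    animal_id: str
    treatment: str
    sex: str
    intercept: float
    contact_shift: float


@dataclass
class Cohort:
    """A generated cohort: long trace table, metadata and ground truth."""

    traces: pd.DataFrame
    metadata: dict[str, ClipMetadata]
    ground_truth: pd.DataFrame


def _simulate_clip_arrays(
    animal: AnimalState,
    clip_id: str,
    texture: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], ClipMetadata, GroundTruth]:
    """Simulate one clip as dense (frames x whiskers) angle arrays per side."""
    dc_mod = config.dc_for_cell((animal.treatment, animal.sex, texture))
    pc_len = int(rng.integers(config.pc_frames[0], config.pc_frames[1] + 1))
    dc_len = int(rng.integers(config.dc_frames[0], config.dc_frames[1] + 1))
    n = pc_len + dc_len
    fs = config.frame_rate
    t = np.arange(n) / fs
    t_c = pc_len / fs

    f_pc = config.whisking_frequency
    f_dc = f_pc * dc_mod.speed_scale
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    pp_pc = config.baseline_peak_to_peak
    pp_dc = pp_pc * dc_mod.amplitude_scale
    shift = (
        dc_mod.mean_shift
        + animal.contact_shift
        + float(rng.normal(0.0, config.clip_contact_shift_sd))
    )

    dc = slice(pc_len, n)
    base = np.full(n, config.baseline_mean_angle + animal.intercept)
    base[dc] += shift

    arrays: dict[str, np.ndarray] = {}
    for side, side_sign, phi in (
        ("left", +1.0, phase),
        ("right", -1.0, phase + config.side_phase_offset),
    ):
        n_wh = int(rng.integers(config.whiskers_per_side[0], config.whiskers_per_side[1] + 1))
        offsets = rng.normal(0.0, config.whisker_offset_sd, size=n_wh)
        # whisk drive, phase-continuous across the contact frame
        drive = np.empty(n)
        drive[:pc_len] = (pp_pc / 2.0) * np.sin(2 * np.pi * f_pc * t[:pc_len] + phi)
        phi_dc = 2 * np.pi * f_pc * t_c + phi
        drive[dc] = (pp_dc / 2.0) * np.sin(2 * np.pi * f_dc * (t[dc] - t_c) + phi_dc)
        col = base + drive
        col[dc] += side_sign * dc_mod.asymmetry_offset / 2.0

        scale = np.ones(n)
        scale[dc] = dc_mod.spread_scale
        angles = col[:, None] + scale[:, None] * offsets[None, :]
        angles += rng.normal(0.0, config.noise_sd, size=angles.shape)
        if config.dropout_prob > 0.0:
            drop = rng.random(angles.shape) < config.dropout_prob
            angles[drop] = np.nan
        arrays[side] = np.clip(angles, 0.0, 180.0)

    meta = ClipMetadata(
        clip_id=clip_id,
        animal_id=animal.animal_id,
        treatment=animal.treatment,
        sex=animal.sex,
        object_texture=texture,
        contact_frame=pc_len,
        frame_rate=fs,
        n_frames=n,
    )
    truth = GroundTruth(
        clip_id=clip_id,
        animal_id=animal.animal_id,
        treatment=animal.treatment,
        sex=animal.sex,
        object_texture=texture,
        pc_frames=pc_len,
        dc_frames=dc_len,
        animal_intercept=animal.intercept,
        animal_contact_shift=animal.contact_shift,
        mean_shift_realized=shift,
        pc_peak_to_peak=pp_pc,
        dc_peak_to_peak=pp_dc,
        asymmetry_offset=dc_mod.asymmetry_offset,
        pc_offset_scale=1.0,
        dc_offset_scale=dc_mod.spread_scale,
        pc_frequency=f_pc,
        dc_frequency=f_dc,
        phase=phase,
    )
    return arrays, meta, truth


def _arrays_to_rows(
    arrays: dict[str, np.ndarray], clip_id: str
) -> pd.DataFrame:
    """Dense per-side arrays -> long-format trace rows (NaN = dropped)."""
    frames_list, sides_list, whiskers, angles = [], [], [], []
    for side in ("left", "right"):
        a = arrays[side]
        n, w = a.shape
        fr = np.repeat(np.arange(n), w)
        wh = np.tile(np.arange(w), n)
        flat = a.ravel()
        keep = np.isfinite(flat)
        frames_list.append(fr[keep])
        sides_list.append(np.full(keep.sum(), side, dtype=object))
        whiskers.append(wh[keep])
        angles.append(flat[keep])
    frames = np.concatenate(frames_list)
    df = pd.DataFrame(
        {
            "clip_id": clip_id,
            "frame_index": frames,
            "side": np.concatenate(sides_list),
            "whisker_id": [f"w{j}" for j in np.concatenate(whiskers)],
            "angle_deg": np.concatenate(angles),
        },
        columns=TRACE_COLUMNS,
    )
    return df


def generate_clip(
    animal: AnimalState,
    clip_id: str,
    texture: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, ClipMetadata, GroundTruth]:
    """Simulate one clip as long-format trace rows plus metadata and truth."""
    arrays, meta, truth = _simulate_clip_arrays(animal, clip_id, texture, config, rng)
    return _arrays_to_rows(arrays, clip_id), meta, truth


def _animal_plan(
    config: SyntheticConfig, seed: int | None
) -> list[tuple[AnimalState, list[tuple[str, str]], np.random.SeedSequence]]:
    """Deterministic cohort layout: animals, their clip/texture plan, substreams."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    cells = sorted(config.animals_per_cell.items())
    n_animals = sum(n for _, n in cells)
    streams = root.spawn(n_animals)
    plan = []
    idx = 0
    for (treatment, sex), n_cell in cells:
        for k in range(n_cell):
            ss = streams[idx]
            idx += 1
            rng = np.random.default_rng(ss)
            animal_id = f"{treatment[0].upper()}{sex[0]}{k + 1:02d}"
            state = AnimalState(
                animal_id=animal_id,
                treatment=treatment,
                sex=sex,
                intercept=float(rng.normal(0.0, config.animal_intercept_sd)),
                contact_shift=float(rng.normal(0.0, config.animal_contact_shift_sd)),
            )
            n_clips = int(
                rng.integers(config.clips_per_animal[0], config.clips_per_animal[1] + 1)
            )
            # sequential object presentation: smooth object first, then textured
            n_smooth = (n_clips + 1) // 2
            clip_plan = [
                (f"{animal_id}_c{j + 1}", "smooth" if j < n_smooth else "textured")
                for j in range(n_clips)
            ]
            plan.append((state, clip_plan, ss))
    return plan


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Simulate a full cohort; deterministic for fixed (config, seed).

    ``seed`` overrides ``config.seed`` when given.  Animals are assigned to
    treatment x sex cells per ``animals_per_cell``; each animal's clips are
    split across the smooth (first) and textured (second) objects.
    """
    trace_parts: list[pd.DataFrame] = []
    metadata: dict[str, ClipMetadata] = {}
    truths: list[dict[str, object]] = []
    for state, clip_plan, ss in _animal_plan(config, seed):
        clip_streams = ss.spawn(len(clip_plan))
        for (clip_id, texture), css in zip(clip_plan, clip_streams):
            rng = np.random.default_rng(css)
            rows, meta, truth = generate_clip(state, clip_id, texture, config, rng)
            trace_parts.append(rows)
            metadata[meta.clip_id] = meta
            truths.append(truth.as_row())
    traces = pd.concat(trace_parts, ignore_index=True)
    return Cohort(
        traces=traces, metadata=metadata, ground_truth=pd.DataFrame(truths)
    )


def simulate_metrics_table(
    config: SyntheticConfig,
    seed: int | None = None,
    kin_config: "kinematics.KinematicsConfig | None" = None,
) -> pd.DataFrame:
    """Simulate a cohort and reduce it straight to the per-clip metrics table.

    Numerically identical to ``generate_cohort`` followed by
    ``kinematics.metrics_table``, but skips the long-format detour, which
    matters when thousands of cohorts are simulated for calibration and
    power studies.
    """
    kin_config = kin_config or kinematics.KinematicsConfig()
    rows = []
    for state, clip_plan, ss in _animal_plan(config, seed):
        clip_streams = ss.spawn(len(clip_plan))
        for (clip_id, texture), css in zip(clip_plan, clip_streams):
            rng = np.random.default_rng(css)
            arrays, meta, _ = _simulate_clip_arrays(state, clip_id, texture, config, rng)
            left = kinematics.side_series_from_array(
                arrays["left"], "left", config.frame_rate
            )
            right = kinematics.side_series_from_array(
                arrays["right"], "right", config.frame_rate
            )
            cm = kinematics.clip_metrics_from_series(left, right, meta, kin_config)
            rows.append(cm.as_row())
    return pd.DataFrame(rows)
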