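"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from whiskkin import synthetic_data as sd
from whiskkin.trace_io import ClipMetadata


@pytest.fixture(scope="session")
def small_config() -> sd.SyntheticConfig:
    """A reduced cohort (3 animals per cell, short clips) for fast tests."""
    return sd.SyntheticConfig(
        animals_per_cell={
            ("MIA", "female"): 3,
            ("MIA", "male"): 3,
            ("control", "female"): 3,
            ("control", "male"): 3,
        },
        clips_per_animal=(2, 3),
        pc_frames=(100, 140),
        dc_frames=(100, 160),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sd.generate_cohort(small_config, seed=11)


@pytest.fixture()
def simple_meta() -> ClipMetadata:
    return ClipMetadata(
        clip_id="clip1",
        animal_id="a1",
        treatment="MIA",
        sex="female",
        object_texture="smooth",
        contact_frame=150,
        frame_rate=500.0,
        n_frames=300,
    )


def make_clip_frame(
    angles_by_side: dict[str, np.ndarray], clip_id: str = "clip1"
) -> pd.DataFrame:
    """Long-format trace rows from dense (frames x whiskers) arrays."""
    rows = []
    for side, arr in angles_by_side.items():
        arr = np.asarray(arr, float)
        for f in range(arr.shape[0]):
            for w in range(arr.shape[1]):
                if np.isfinite(arr[f, w]):
                    rows.append(
                        {
                            "clip_id": clip_id,
                            "frame_index": f,
                            "side": side,
                            "whisker_id": f"w{w}",
                            "angle_deg": arr[f, w],
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def kr_fixture() -> pd.DataFrame:
    """Unbalanced 2x2 cohort with 10 animals and 1-4 clips each.

    Frozen reference values for this exact table (seed 42) were computed
    with an independent mixed-model stack (lme4 REML + Kenward-Roger
    type-III tests + Tukey-adjusted estimated-marginal-mean contrasts) and
    live in test_mixed_stats.py.
    """
    rng = np.random.default_rng(42)
    rows = []
    for i in range(10):
        tr = "MIA" if i < 5 else "control"
        u = rng.normal(0, 1.5)
        k = rng.integers(1, 5)
        for j in range(k):
            tex = "smooth" if j < (k + 1) // 2 else "textured"
            y = (
                10.0
                + (1.0 if tr == "MIA" else 0.0)
                + (0.8 if tex == "textured" else 0.0)
                + u
                + rng.normal(0, 1.2)
            )
            rows.append(
                dict(animal_id=f"a{i}", treatment=tr, object_texture=tex, y=y)
            )
    return pd.DataFrame(rows)
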