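"""Metric definitions checked against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskkin import kinematics as kin
from whiskkin.kinematics import (
    EmptySegmentError,
    KinematicsConfig,
    SideAngleSeries,
    angular_velocity,
    compute_clip_metrics,
    mean_angular_position,
    movement_speeds,
    per_side_series,
    smooth_series,
    whisker_amplitude,
    whisker_asymmetry,
    whisker_spread,
)
from whiskkin.trace_io import ClipMetadata

from conftest import make_clip_frame

SQRT8 = 2.0 * math.sqrt(2.0)


def _series(values, side="left", fs=500.0, sd=None, count=None):
    values = np.asarray(values, float)
    n = len(values)
    return SideAngleSeries(
        side=side,
        mean_angle=values,
        sd=np.full(n, np.nan) if sd is None else np.asarray(sd, float),
        count=np.ones(n, dtype=int) if count is None else np.asarray(count),
        frame_rate=fs,
    )


# --- per-frame aggregation -------------------------------------------------


def test_per_side_series_mean_and_sample_sd(simple_meta):
    # left whiskers at 80/90/100 deg: mean 90, sample SD 10
    arr = np.tile([80.0, 90.0, 100.0], (simple_meta.n_frames, 1))
    df = make_clip_frame({"left": arr, "right": arr + 5.0})
    series = per_side_series(df, simple_meta)
    np.testing.assert_allclose(series["left"].mean_angle, 90.0)
    np.testing.assert_allclose(series["left"].sd, 10.0)
    np.testing.assert_allclose(series["right"].mean_angle, 95.0)
    assert (series["left"].count == 3).all()


def test_per_side_series_single_whisker_has_no_sd(simple_meta):
    arr = np.full((simple_meta.n_frames, 1), 95.0)
    df = make_clip_frame({"left": arr, "right": arr})
    series = per_side_series(df, simple_meta)
    np.testing.assert_allclose(series["left"].mean_angle, 95.0)
    assert np.isnan(series["left"].sd).all()


def test_per_side_series_identical_whiskers_zero_sd(simple_meta):
    arr = np.full((simple_meta.n_frames, 4), 101.5)
    df = make_clip_frame({"left": arr, "right": arr})
    series = per_side_series(df, simple_meta)
    np.testing.assert_allclose(series["left"].sd, 0.0, atol=1e-10)


def test_per_side_series_matches_dense_array_path(simple_meta):
    rng = np.random.default_rng(3)
    arr = {s: 90 + 10 * rng.standard_normal((simple_meta.n_frames, 5)) for s in ("left", "right")}
    df = make_clip_frame(arr)
    from_table = per_side_series(df, simple_meta)
    for side in ("left", "right"):
        direct = kin.side_series_from_array(arr[side], side, simple_meta.frame_rate)
        np.testing.assert_allclose(from_table[side].mean_angle, direct.mean_angle, atol=1e-10)
        np.testing.assert_allclose(from_table[side].sd, direct.sd, atol=1e-9)


# --- smoothing and differentiation ----------------------------------------


def test_smoothing_reproduces_quadratic_exactly():
    t = np.arange(100, dtype=float)
    x = 3.0 + 0.5 * t - 0.01 * t**2
    np.testing.assert_allclose(smooth_series(x, 15, 2), x, atol=1e-8)


def test_smoothing_preserves_constants_and_length():
    x = np.full(60, 42.0)
    out = smooth_series(x)
    assert len(out) == 60
    np.testing.assert_allclose(out, 42.0)


def test_smoothing_contracts_noise_variance():
    rng = np.random.default_rng(0)
    t = np.arange(400) / 500.0
    x = 20 * np.sin(2 * np.pi * 8 * t) + rng.normal(0, 5, size=400)
    assert np.var(smooth_series(x)) < np.var(x)


def test_smoothing_rejects_short_series():
    with pytest.raises(ValueError, match="lower the window"):
        smooth_series(np.arange(10.0), 15, 2)


def test_smoothing_handles_nan_gaps():
    x = np.arange(100, dtype=float)
    x[40:45] = np.nan
    out = smooth_series(x)
    assert np.isnan(out[40:45]).all()
    np.testing.assert_allclose(out[:30], x[:30], atol=1e-8)


def test_velocity_of_linear_ramp():
    x = 0.5 * np.arange(200)  # 0.5 deg/frame
    v = angular_velocity(x, 500.0)
    np.testing.assert_allclose(v, 250.0)


def test_velocity_of_constant_is_zero():
    np.testing.assert_allclose(angular_velocity(np.full(50, 90.0), 500.0), 0.0)


def test_velocity_of_sine_matches_derivative():
    fs, f = 500.0, 8.0
    t = np.arange(1000) / fs
    x = 100 + 20 * np.sin(2 * np.pi * f * t)
    v = angular_velocity(x, fs)
    expected = 20 * 2 * np.pi * f * np.cos(2 * np.pi * f * t)
    # central differences carry a sinc(w*dt) attenuation of ~0.2% here
    np.testing.assert_allclose(v[2:-2], expected[2:-2], atol=2.5)


# --- the six metrics -------------------------------------------------------


def test_mean_angular_position_averages_sides():
    left = _series(np.full(100, 110.0))
    right = _series(np.full(100, 90.0), side="right")
    value, single = mean_angular_position(left, right)
    assert value == pytest.approx(100.0)
    assert not single


def test_mean_angular_position_sinusoid_over_whole_periods():
    t = np.arange(125) / 500.0  # exactly 2 periods at 8 Hz
    x = 100 + 20 * np.sin(2 * np.pi * 8 * t)
    value, _ = mean_angular_position(_series(x), _series(x, side="right"))
    assert value == pytest.approx(100.0, abs=1e-6)


def test_mean_angular_position_single_side_flagged():
    left = _series(np.full(100, 110.0))
    right = _series(np.full(100, np.nan), side="right")
    value, single = mean_angular_position(left, right)
    assert value == pytest.approx(110.0)
    assert single


def test_amplitude_recovers_peak_to_peak_of_sinusoid():
    fs, f, pp = 500.0, 8.0, 40.0
    n = int(4 * fs / f)  # 4 whole periods
    t = np.arange(n) / fs
    x = 100 + (pp / 2) * np.sin(2 * np.pi * f * t)
    amp = whisker_amplitude(_series(x), _series(x, side="right"))
    assert amp == pytest.approx(pp, abs=0.2)


def test_amplitude_matches_brute_force_sd():
    rng = np.random.default_rng(5)
    x = 90 + 7 * rng.standard_normal(10)
    amp = whisker_amplitude(_series(x), _series(x, side="right"))
    assert amp == pytest.approx(SQRT8 * np.std(x, ddof=1), rel=1e-12)


def test_amplitude_of_constant_is_zero():
    amp = whisker_amplitude(_series(np.full(50, 90.0)), _series(np.full(50, 90.0), side="right"))
    assert amp == 0.0


def test_asymmetry_constant_offset():
    unsigned, signed = whisker_asymmetry(
        _series(np.full(80, 110.0)), _series(np.full(80, 90.0), side="right")
    )
    assert unsigned == pytest.approx(20.0)
    assert signed == pytest.approx(20.0)


def test_asymmetry_zero_when_sides_equal():
    x = 100 + 10 * np.sin(np.linspace(0, 20, 200))
    unsigned, _ = whisker_asymmetry(_series(x), _series(x, side="right"))
    assert unsigned == pytest.approx(0.0, abs=1e-12)


def test_asymmetry_antiphase_matches_framewise_oracle():
    t = np.arange(250) / 500.0
    left = 100 + 10 * np.sin(2 * np.pi * 8 * t)
    right = 100 - 10 * np.sin(2 * np.pi * 8 * t)
    unsigned, signed = whisker_asymmetry(_series(left), _series(right, side="right"))
    assert signed == pytest.approx(np.mean(left - right), rel=1e-12)
    assert unsigned == abs(signed)


def test_spread_hand_computed():
    n = 50
    left = kin.side_series_from_array(np.tile([80.0, 90.0, 100.0], (n, 1)), "left", 500.0)
    right = kin.side_series_from_array(np.tile([85.0, 90.0, 95.0], (n, 1)), "right", 500.0)
    assert whisker_spread(left, right) == pytest.approx((10.0 + 5.0) / 2.0)


def test_spread_requires_multi_whisker_frames():
    left = _series(np.full(50, 90.0))
    right = _series(np.full(50, 90.0), side="right")
    with pytest.raises(EmptySegmentError):
        whisker_spread(left, right)


def test_speeds_on_monotone_ramp():
    x = 60 + 0.5 * np.arange(300)  # rises 0.5 deg/frame
    pro, ret = movement_speeds(_series(x), _series(x, side="right"))
    assert pro == pytest.approx(250.0, rel=1e-6)
    assert math.isnan(ret)


def test_speeds_symmetric_triangle_wave():
    cycle = np.concatenate([np.linspace(80, 120, 26), np.linspace(120, 80, 26)[1:]])
    x = np.tile(cycle[:-1], 6)
    pro, ret = movement_speeds(_series(x), _series(x, side="right"))
    assert pro == pytest.approx(ret, rel=0.05)


def test_speeds_of_constant_series_are_missing():
    x = np.full(100, 90.0)
    pro, ret = movement_speeds(_series(x), _series(x, side="right"))
    assert math.isnan(pro) and math.isnan(ret)


# --- invariance properties -------------------------------------------------


@st.composite
def random_clip_arrays(draw):
    n = draw(st.integers(40, 80))
    w = draw(st.integers(2, 4))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    return {
        "left": 100 + 15 * rng.standard_normal((n, w)),
        "right": 95 + 15 * rng.standard_normal((n, w)),
    }


def _metric_vector(arrays, fs=500.0, window=7):
    left = kin.side_series_from_array(arrays["left"], "left", fs)
    right = kin.side_series_from_array(arrays["right"], "right", fs)
    cfg = KinematicsConfig(smoothing_window=window)
    mean, _ = mean_angular_position(left, right)
    unsigned, _ = whisker_asymmetry(left, right)
    pro, ret = movement_speeds(left, right, cfg)
    return {
        "mean": mean,
        "amplitude": whisker_amplitude(left, right),
        "asymmetry": unsigned,
        "spread": whisker_spread(left, right),
        "pro": pro,
        "ret": ret,
    }


@settings(max_examples=25, deadline=None, derandomize=True)
@given(random_clip_arrays(), st.floats(-30, 30))
def test_translation_invariance(arrays, offset):
    """A constant angle offset moves the mean and nothing else."""
    base = _metric_vector(arrays)
    shifted = _metric_vector({s: a + offset for s, a in arrays.items()})
    assert shifted["mean"] == pytest.approx(base["mean"] + offset, abs=1e-8)
    for key in ("amplitude", "asymmetry", "spread", "pro", "ret"):
        assert shifted[key] == pytest.approx(base[key], rel=1e-9, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(random_clip_arrays())
def test_time_reversal_swaps_speeds(arrays):
    base = _metric_vector(arrays)
    rev = _metric_vector({s: a[::-1] for s, a in arrays.items()})
    assert rev["pro"] == pytest.approx(base["ret"], rel=1e-9)
    assert rev["ret"] == pytest.approx(base["pro"], rel=1e-9)
    for key in ("mean", "amplitude", "asymmetry", "spread"):
        assert rev[key] == pytest.approx(base[key], rel=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(random_clip_arrays())
def test_positional_metrics_match_brute_force(arrays):
    """Frame-wise brute-force recomputation of the positional metrics."""
    left, right = arrays["left"], arrays["right"]
    got = _metric_vector(arrays)
    lm, rm = left.mean(axis=1), right.mean(axis=1)
    assert got["mean"] == pytest.approx((lm.mean() + rm.mean()) / 2, rel=1e-10)
    amp = (SQRT8 * lm.std(ddof=1) + SQRT8 * rm.std(ddof=1)) / 2
    assert got["amplitude"] == pytest.approx(amp, rel=1e-10)
    assert got["asymmetry"] == pytest.approx(abs((lm - rm).mean()), rel=1e-9, abs=1e-9)
    sds = np.concatenate([left.std(axis=1, ddof=1), right.std(axis=1, ddof=1)])
    assert got["spread"] == pytest.approx(sds.mean(), rel=1e-10)


# --- per-clip assembly -----------------------------------------------------


def test_delta_is_pc_minus_dc_exactly(simple_meta):
    rng = np.random.default_rng(9)
    arrays = {s: 95 + 8 * rng.standard_normal((simple_meta.n_frames, 4)) for s in ("left", "right")}
    cm = compute_clip_metrics(make_clip_frame(arrays), simple_meta)
    for name in ("mean_angle", "amplitude", "asymmetry", "spread"):
        assert cm.delta[name] == pytest.approx(
            getattr(cm.pc, name) - getattr(cm.dc, name), rel=1e-12
        )


def _whole_period_meta() -> ClipMetadata:
    # 125-frame segments are exactly 2 whisk periods at 8 Hz / 500 fps, so
    # segment means of the sinusoidal drive carry no partial-cycle bias
    return ClipMetadata("clip1", "a1", "MIA", "female", "smooth", 125, 500.0, 250)


def test_stationary_clip_has_near_zero_deltas():
    meta = _whole_period_meta()
    t = np.arange(meta.n_frames) / meta.frame_rate
    drive = 100 + 20 * np.sin(2 * np.pi * 8 * t)
    arrays = {s: np.tile(drive[:, None], (1, 3)) + [[0.0, 4.0, -4.0]] for s in ("left", "right")}
    cm = compute_clip_metrics(make_clip_frame(arrays), meta)
    assert cm.delta["mean_angle"] == pytest.approx(0.0, abs=0.5)
    assert cm.delta["amplitude"] == pytest.approx(0.0, abs=0.5)
    assert cm.delta["spread"] == pytest.approx(0.0, abs=1e-9)
    assert cm.delta["protraction_speed"] == pytest.approx(0.0, abs=10.0)


def test_dc_mean_shift_gives_negative_delta():
    """A +5 deg during-contact shift appears as delta = PC - DC = -5."""
    meta = _whole_period_meta()
    base = np.full((meta.n_frames, 3), 100.0)
    base[meta.contact_frame :, :] += 5.0
    wobble = 10 * np.sin(2 * np.pi * 8 * np.arange(meta.n_frames) / meta.frame_rate)
    arrays = {s: base + wobble[:, None] for s in ("left", "right")}
    cm = compute_clip_metrics(make_clip_frame(arrays), meta)
    assert cm.delta["mean_angle"] == pytest.approx(-5.0, abs=0.5)
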