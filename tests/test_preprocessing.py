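"""Gravity estimation, channel assembly and normalization."""

import math
import warnings

import numpy as np
import pytest

from wristdtw.data_io import STANDARD_GRAVITY, ImuTrial
from wristdtw.preprocessing import (
    AxisScales,
    ChannelMatrix,
    ConfigurationError,
    DegenerateInputError,
    assemble_channels,
    channel_names,
    compute_axis_scales,
    estimate_gravity,
    lowpass_gravity,
    normalize,
    preprocess_trial,
)
from wristdtw.synthetic import (
    ZERO_NOISE,
    AngleProfile,
    MovementTemplate,
    TranslationProfile,
    simulate_trial,
    static_template,
    trial_kinematics,
)


def _direction_error_deg(est, true):
    cos = np.sum(est * true, axis=1) / (
        np.linalg.norm(est, axis=1) * np.linalg.norm(true, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def test_static_level_trial_recovers_gravity():
    tr = simulate_trial(static_template(0.0, 0.0, 0.0), ZERO_NOISE, 0)
    _, gravity, lin_acc = estimate_gravity(tr)
    after_1s = slice(100, None)
    assert np.allclose(gravity[after_1s], [0, 0, STANDARD_GRAVITY], atol=0.05)
    assert np.abs(lin_acc[after_1s]).max() < 0.05


def test_static_tilt_30deg_recovers_direction():
    # tilt 30 degrees about x: specific force (0, g sin30 .. no: rotated)
    tr = simulate_trial(static_template(math.radians(30), 0.0, 0.0), ZERO_NOISE, 0)
    _, gravity, _ = estimate_gravity(tr)
    err = _direction_error_deg(gravity[100:], tr.acc[100:])
    assert err.max() < 1.0


@pytest.mark.parametrize("seed", range(6))
def test_static_random_orientations_converge(seed, rng):
    r = np.random.default_rng(seed)
    tpl = static_template(*r.uniform(-math.pi, math.pi, 3))
    tr = simulate_trial(tpl, ZERO_NOISE, seed)
    _, gravity, _ = estimate_gravity(tr)
    err = _direction_error_deg(gravity[100:], tr.acc[100:])
    assert err.max() < 1.0
    mags = np.linalg.norm(gravity[100:], axis=1)
    assert np.abs(mags / STANDARD_GRAVITY - 1.0).max() < 0.02


def test_rotating_trial_tracks_true_gravity():
    """Ideal signals from a known rotation: the filter's gravity direction
    stays within 2 degrees RMS of the ground truth."""
    tpl = MovementTemplate(
        task_id=0, movement_type="rot", quality="correct",
        roll=AngleProfile(bump=0.6), pitch=AngleProfile(ramp=-0.8),
        yaw=AngleProfile(ramp=1.2), duration_sd=0.0,
    )
    tr = simulate_trial(tpl, ZERO_NOISE, 5)
    t, R, _, _ = trial_kinematics(tpl, tr.duration, 100.0, 1.0, 0.0)
    true_g = np.einsum("tji,j->ti", R, [0.0, 0.0, 1.0]) * STANDARD_GRAVITY
    _, gravity, _ = estimate_gravity(tr)
    err = _direction_error_deg(gravity, true_g)
    assert np.sqrt(np.mean(err**2)) < 2.0


def test_gravity_plus_linear_acceleration_reconstructs_raw(static_trial):
    _, gravity, lin_acc = estimate_gravity(static_trial)
    assert np.abs(gravity + lin_acc - static_trial.acc).max() < 1e-9


def test_all_zero_accelerometer_is_degenerate(rng):
    n = 120
    tr = ImuTrial(
        "P", 1, "lab", "m", "correct", np.arange(n) / 100.0,
        np.zeros((n, 3)), np.zeros((n, 3)), np.zeros((n, 3)),
    )
    with pytest.raises(DegenerateInputError):
        estimate_gravity(tr)


def test_lowpass_gravity_static(static_trial):
    gravity, lin_acc = lowpass_gravity(static_trial)
    err = _direction_error_deg(gravity, static_trial.acc)
    assert err.max() < 1.0
    assert np.abs(lin_acc).max() < 0.05


# ---------------------------------------------------------------------------
# channel assembly
# ---------------------------------------------------------------------------

def test_assemble_single_group_is_raw_stream(static_trial):
    pre = preprocess_trial(static_trial)
    m = assemble_channels(pre, ("gyro",))
    assert m.channel_names == ("gyro_x", "gyro_y", "gyro_z")
    assert np.array_equal(m.values, static_trial.gyro)


def test_assemble_canonical_order_and_width(static_trial):
    pre = preprocess_trial(static_trial)
    m = assemble_channels(pre, ("gyro", "lin_acc", "grav"))  # any input order
    assert m.values.shape[1] == 9
    assert m.channel_names == channel_names(("lin_acc", "grav", "gyro"))


def test_assemble_empty_channels_rejected(static_trial):
    pre = preprocess_trial(static_trial)
    with pytest.raises(ConfigurationError):
        assemble_channels(pre, ())


def test_axis_scales_sample_convention_and_constant_fallback():
    vals = np.column_stack([[0.0, 2.0], [1.0, 1.0], [3.0, 4.0]])
    m = ChannelMatrix(vals, ("c1", "c2", "c3"), 100.0)
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        scales = compute_axis_scales([m])
        assert any("constant" in str(x.message) for x in w)
    assert scales.sigma[0] == pytest.approx(math.sqrt(2.0))  # {0,2}, ddof=1
    assert scales.sigma[1] == 1.0  # constant channel falls back to 1
    # lab-concatenated channels end up with unit sample variance
    normed = normalize(m, scales)
    assert normed.values[:, 0].std(ddof=1) == pytest.approx(1.0)


def test_normalize_division_only():
    m = ChannelMatrix(np.array([[2.0, 10.0, 1.0], [4.0, 10.0, 2.0]]), ("a", "b", "c"), 100.0)
    s = AxisScales(np.array([2.0, 5.0, 1.0]), ("a", "b", "c"))
    out = normalize(m, s)
    assert np.array_equal(out.values, [[1.0, 2.0, 1.0], [2.0, 2.0, 2.0]])
    # unit scales are the identity; normalization is idempotent under them
    ones = AxisScales(np.ones(3), ("a", "b", "c"))
    again = normalize(out, ones)
    assert np.array_equal(again.values, out.values)


def test_normalize_channel_mismatch_rejected():
    m = ChannelMatrix(np.ones((4, 3)), ("x", "y", "z"), 100.0)
    s = AxisScales(np.ones(3), ("a", "b", "c"))
    with pytest.raises(ValueError):
        normalize(m, s)


def test_normalization_commutes_with_channel_selection(static_trial):
    pre = preprocess_trial(static_trial)
    full = assemble_channels(pre, ("lin_acc", "grav", "gyro"))
    # perturb so no channel is constant
    r = np.random.default_rng(0)
    full = ChannelMatrix(full.values + r.normal(0, 0.1, full.values.shape),
                         full.channel_names, full.fs)
    scales = compute_axis_scales([full])
    normed_then_selected = normalize(full, scales).values[:, 6:9]
    sub = ChannelMatrix(full.values[:, 6:9], full.channel_names[6:9], full.fs)
    selected_then_normed = normalize(sub, scales.subset(full.channel_names[6:9])).values
    assert np.allclose(normed_then_selected, selected_then_normed, rtol=1e-12)
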