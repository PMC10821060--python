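"""Physical consistency and determinism of the synthetic generator."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wristdtw.data_io import STANDARD_GRAVITY
from wristdtw.synthetic import (
    DEFAULT_INCORRECT_TYPES,
    G_UP,
    ZERO_NOISE,
    AngleProfile,
    MovementTemplate,
    NoiseModel,
    SyntheticConfig,
    TranslationProfile,
    apply_modifier,
    correct_template,
    gyro_only_templates,
    simulate_participant,
    simulate_trial,
    static_template,
    task_templates,
    trial_kinematics,
)


def test_zero_motion_template_is_static():
    tr = simulate_trial(static_template(0.3, -0.2, 0.5), ZERO_NOISE, 0)
    assert np.allclose(tr.acc, tr.acc[0])
    assert np.allclose(np.linalg.norm(tr.acc, axis=1), STANDARD_GRAVITY)
    assert np.all(tr.gyro == 0.0)


def test_same_seed_bit_identical_trials():
    tpl = correct_template(2)
    a = simulate_trial(tpl, NoiseModel(), 99)
    b = simulate_trial(tpl, NoiseModel(), 99)
    assert np.array_equal(a.t, b.t)
    assert np.array_equal(a.acc, b.acc)
    assert np.array_equal(a.gyro, b.gyro)
    assert np.array_equal(a.mag, b.mag)
    c = simulate_trial(tpl, NoiseModel(), 100)
    assert not np.array_equal(a.acc, c.acc)


def test_accelerometer_is_exact_specific_force_at_zero_noise():
    tpl = correct_template(1)
    tr = simulate_trial(tpl, ZERO_NOISE, 3)
    rng = np.random.default_rng(np.random.SeedSequence(3))
    dur = float(np.clip(rng.normal(tpl.duration_mean, tpl.duration_sd), 1.0, 6.0))
    _, R, _, a_world = trial_kinematics(tpl, dur, 100.0, 1.0, 0.0)
    expected = np.einsum("tji,tj->ti", R, a_world + G_UP[None, :])
    assert np.abs(tr.acc - expected).max() == 0.0


@pytest.mark.parametrize("task", [1, 2, 3, 4])
def test_gyro_consistent_with_rotation_finite_difference(task):
    """Differentiating the emitted rotation numerically recovers the
    emitted gyroscope stream (zero noise)."""
    tpl = correct_template(task)
    tr = simulate_trial(tpl, ZERO_NOISE, 11)
    rng = np.random.default_rng(np.random.SeedSequence(11))
    dur = float(np.clip(rng.normal(tpl.duration_mean, tpl.duration_sd), 1.0, 6.0))
    _, R, omega, _ = trial_kinematics(tpl, dur, 100.0, 1.0, 0.0)
    assert np.array_equal(tr.gyro, omega)
    dR = np.einsum("tij,tik->tjk", R[:-1], R[1:])  # R_k^T R_{k+1}
    fd = Rotation.from_matrix(dR).as_rotvec() * 100.0  # midpoint rate
    mid = 0.5 * (omega[:-1] + omega[1:])
    rms = np.sqrt(np.mean((fd - mid) ** 2))
    assert rms < 1e-3


def test_magnetometer_yaw_offset_changes_home_field():
    tpl = static_template(0.1, 0.2, 0.3)
    lab = simulate_trial(tpl, ZERO_NOISE, 0, mag_yaw_offset_deg=0.0)
    home = simulate_trial(tpl, ZERO_NOISE, 0, mag_yaw_offset_deg=60.0)
    assert not np.allclose(lab.mag, home.mag)
    # field magnitude is invariant under the yaw offset
    assert np.allclose(
        np.linalg.norm(lab.mag, axis=1), np.linalg.norm(home.mag, axis=1)
    )


def test_incomplete_modifier_truncates():
    tpl = apply_modifier(correct_template(2), "incomplete")
    full = simulate_trial(correct_template(2), ZERO_NOISE, 5)
    cut = simulate_trial(tpl, ZERO_NOISE, 5)
    assert cut.n_samples < full.n_samples
    assert 0.3 < cut.n_samples / full.n_samples < 0.8


def test_nonparetic_assist_is_nearly_stationary():
    tpl = apply_modifier(correct_template(1), "nonparetic_assist")
    quiet = simulate_trial(tpl, ZERO_NOISE, 5)
    active = simulate_trial(correct_template(1), ZERO_NOISE, 5)
    assert np.abs(quiet.gyro).max() < 0.2 * np.abs(active.gyro).max()


def test_task_templates_cover_both_qualities():
    for task in (1, 2, 3, 4):
        tpls = task_templates(task)
        assert tpls[0].quality == "correct"
        assert all(t.quality == "incorrect" for t in tpls[1:])
        assert len(tpls) == 1 + len(DEFAULT_INCORRECT_TYPES[task])


def test_default_participant_composition():
    cfg = SyntheticConfig(tasks=(1, 2))
    lab, home, truth = simulate_participant(cfg, 0)
    for task in (1, 2):
        lab_task = lab.by_task(task)
        assert len(lab_task) == 6 + 2 * 3  # 6 correct + 2 incorrect types x 3
        assert len(home.by_task(task)) == 75
    lab.validate_lab_reference()
    assert len(truth) == 150
    assert set(truth.quality) == {"correct", "incorrect"}
    # home trials themselves are unlabeled; truth lives in the table
    assert all(t.quality == "unknown" for t in home.trials)


def test_home_only_type_absent_from_lab():
    cfg = SyntheticConfig(
        tasks=(3,), home_only_type="nonparetic_assist", home_only_fraction=0.2
    )
    lab, home, truth = simulate_participant(cfg, 1)
    lab_types = {t.movement_type for t in lab.trials}
    assert "nonparetic_assist" not in lab_types
    assert (truth.movement_type == "nonparetic_assist").sum() > 0


def test_participant_determinism_and_seed_sensitivity():
    cfg = SyntheticConfig(tasks=(1,), home_trials_per_task=5)
    lab1, home1, truth1 = simulate_participant(cfg, 7)
    lab2, home2, truth2 = simulate_participant(cfg, 7)
    assert all(
        np.array_equal(a.acc, b.acc) for a, b in zip(lab1.trials, lab2.trials)
    )
    assert truth1.equals(truth2)
    lab3, _, _ = simulate_participant(cfg, 8)
    assert not np.array_equal(lab1.trials[0].acc, lab3.trials[0].acc)


def test_gyro_only_templates_share_everything_but_yaw():
    correct, wiggle = gyro_only_templates()
    assert correct.roll == wiggle.roll
    assert correct.pitch == wiggle.pitch
    assert correct.translation == wiggle.translation
    assert correct.yaw != wiggle.yaw


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SyntheticConfig(lab_trials_per_incorrect=1)
    with pytest.raises(ValueError):
        SyntheticConfig(home_correct_fraction=1.5)
    with pytest.raises(ValueError):
        NoiseModel(acc_noise=-0.1)
    with pytest.raises(ValueError):
        MovementTemplate(1, "x", "correct", duration_mean=1.0, duration_sd=0.5)
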