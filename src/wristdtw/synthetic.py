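"""Physically consistent synthetic wrist-IMU sessions.

The generator emulates the study design this pipeline targets: a
participant wears a 9-axis sensor on the paretic wrist, performs a small
labeled lab session per task (a correct movement type plus compensatory
variants, a handful of trials each), then a large unlabeled home session
(~75 trials per task) whose ground truth is kept in a separate table.

Each trial is built from a rigid-body movement template: parametric Euler
angle trajectories (roll/pitch/yaw over normalized time, built from
minimum-jerk smoothsteps and mid-movement bumps) and a minimum-jerk
translation with a vertical peak.  The emitted signals are derived
analytically from that template, so they are mutually consistent:

* accelerometer = R^T (a_world + g_up) + noise   (specific force)
* gyroscope     = true body-frame angular velocity + bias walk + noise
* magnetometer  = R^T Rz(yaw_offset) m_earth + noise

where R(t) = Rz(yaw) Ry(pitch) Rx(roll) maps sensor to world, g_up =
(0, 0, +9.80665) m/s^2, and the home session applies a yaw offset to the
earth field to mimic the lab-vs-home heading change that makes the
magnetometer an unreliable movement cue.

Compensatory movement types are encoded as template modifiers: trunk or
shoulder involvement adds a pitch ramp / roll offset and a raised path;
a compensatory grip alters the final wrist-extension angle and raises
peak acceleration; "unable to complete" truncates the movement; a
nonparetic-hand assist leaves the paretic wrist nearly stationary.

Randomness: one root seed; every trial draws from an independent
generator seeded with SeedSequence([root, task, phase, index]) so any
subset of trials regenerates identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .data_io import (
    QUALITY_CORRECT,
    QUALITY_INCORRECT,
    QUALITY_UNKNOWN,
    STANDARD_GRAVITY,
    ImuTrial,
    Session,
)

G_UP = np.array([0.0, 0.0, STANDARD_GRAVITY])
# earth magnetic field, z-up world frame: north + downward dip
MAG_FIELD_UT = 50.0
MAG_INCLINATION_RAD = math.radians(60.0)
M_EARTH = np.array(
    [
        MAG_FIELD_UT * math.cos(MAG_INCLINATION_RAD),
        0.0,
        -MAG_FIELD_UT * math.sin(MAG_INCLINATION_RAD),
    ]
)

# phase codes for the per-trial seed scheme
_PHASE_LAB = 0
_PHASE_HOME = 1
_PHASE_MIX = 2


@dataclass(frozen=True)
class AngleProfile:
    """One Euler angle over normalized time u in [0, 1]:

    angle(u) = offset + ramp * s(u) + bump * sin^2(pi u)

    with s the minimum-jerk smoothstep 6u^5 - 15u^4 + 10u^3.  Twice
    differentiable, zero velocity at both ends."""

    offset: float = 0.0  # rad
    ramp: float = 0.0  # rad
    bump: float = 0.0  # rad


@dataclass(frozen=True)
class TranslationProfile:
    """Minimum-jerk displacement plus a vertical sin^2 peak."""

    displacement: tuple = (0.0, 0.0, 0.0)  # m, endpoint - start
    peak_height: float = 0.0  # m


@dataclass(frozen=True)
class MovementTemplate:
    task_id: int
    movement_type: str
    quality: str
    roll: AngleProfile = AngleProfile()
    pitch: AngleProfile = AngleProfile()
    yaw: AngleProfile = AngleProfile()
    translation: TranslationProfile = TranslationProfile()
    duration_mean: float = 3.0  # s
    duration_sd: float = 0.3  # s
    truncate_range: tuple | None = None  # (lo, hi) fraction of the movement
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_sd >= self.duration_mean / 3:
            raise ValueError("duration sd must be < mean/3")


@dataclass(frozen=True)
class NoiseModel:
    acc_noise: float = 0.05  # m/s^2
    gyro_noise: float = 0.01  # rad/s
    gyro_bias_walk: float = 1e-3  # rad/s per sqrt(s)
    mag_noise: float = 0.5  # uT
    amplitude_sd: float = 0.1  # unitless multiplier sd
    time_warp_sd: float = 0.08  # smooth monotone time-warp strength

    def __post_init__(self) -> None:
        for name in ("acc_noise", "gyro_noise", "gyro_bias_walk", "mag_noise",
                     "amplitude_sd", "time_warp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    tasks: tuple = (1, 2, 3, 4)
    lab_trials_correct: int = 6
    lab_trials_per_incorrect: int = 3
    home_trials_per_task: int = 75
    home_correct_fraction: float = 0.7
    effect_scale: float = 1.0  # multiplies compensatory-modifier magnitudes
    noise: NoiseModel = NoiseModel()
    fs: float = 100.0
    home_mag_yaw_offset_deg: float = 60.0
    home_only_type: str | None = None  # e.g. "nonparetic_assist"
    home_only_fraction: float = 0.1  # share of incorrect home trials
    participant_id: str = "P01"

    def __post_init__(self) -> None:
        if not (2 <= self.lab_trials_per_incorrect <= 20):
            raise ValueError("lab trials per type must be within [2, 20]")
        if not (2 <= self.lab_trials_correct <= 20):
            raise ValueError("lab trials per type must be within [2, 20]")
        if not 0.0 <= self.home_correct_fraction <= 1.0:
            raise ValueError("home_correct_fraction must be in [0, 1]")
        if not 0.0 <= self.home_only_fraction <= 1.0:
            raise ValueError("home_only_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# profile evaluation (analytic derivatives, warp chain rule)
# ---------------------------------------------------------------------------

def _smoothstep(v):
    s = ((6.0 * v - 15.0) * v + 10.0) * v**3
    s1 = ((30.0 * v - 60.0) * v + 30.0) * v**2
    s2 = ((120.0 * v - 180.0) * v + 60.0) * v
    return s, s1, s2


def _bump(v):
    b = np.sin(np.pi * v) ** 2
    b1 = np.pi * np.sin(2.0 * np.pi * v)
    b2 = 2.0 * np.pi**2 * np.cos(2.0 * np.pi * v)
    return b, b1, b2


def _angle_series(profile: AngleProfile, v, v1, duration, amp):
    """angle(t) and d(angle)/dt on the warped time base."""
    s, s1, _ = _smoothstep(v)
    b, b1, _ = _bump(v)
    ang = profile.offset + amp * (profile.ramp * s + profile.bump * b)
    rate = amp * (profile.ramp * s1 + profile.bump * b1) * v1 / duration
    return ang, rate


def _translation_accel(profile: TranslationProfile, v, v1, v2, duration, amp):
    """World-frame acceleration of the minimum-jerk + peak path."""
    _, s1, s2 = _smoothstep(v)
    _, b1, b2 = _bump(v)
    disp = amp * np.asarray(profile.displacement)
    h = amp * profile.peak_height
    # d^2/dt^2 f(v(u(t))) = [f''(v) v'^2 + f'(v) v''] / T^2
    core = s2 * v1**2 + s1 * v2
    a = disp[None, :] * core[:, None] / duration**2
    a[:, 2] += h * (b2 * v1**2 + b1 * v2) / duration**2
    return a


def _body_rates(roll, pitch, roll_rate, pitch_rate, yaw_rate):
    """ZYX Euler-rate to body angular velocity."""
    wx = roll_rate - yaw_rate * np.sin(pitch)
    wy = pitch_rate * np.cos(roll) + yaw_rate * np.cos(pitch) * np.sin(roll)
    wz = -pitch_rate * np.sin(roll) + yaw_rate * np.cos(pitch) * np.cos(roll)
    return np.column_stack([wx, wy, wz])


def trial_kinematics(
    template: MovementTemplate,
    duration: float,
    fs: float,
    amp: float = 1.0,
    warp: float = 0.0,
):
    """Ground-truth rotation matrices, body rates and world acceleration
    for one realization of a template.  Exposed for oracle tests."""
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    total = t[-1]
    u = t / total
    v = u + warp * np.sin(np.pi * u)
    v1 = 1.0 + warp * np.pi * np.cos(np.pi * u)
    v2 = -warp * np.pi**2 * np.sin(np.pi * u)

    amp_total = amp * template.amplitude_scale
    roll, roll_rate = _angle_series(template.roll, v, v1, total, amp_total)
    pitch, pitch_rate = _angle_series(template.pitch, v, v1, total, amp_total)
    yaw, yaw_rate = _angle_series(template.yaw, v, v1, total, amp_total)

    # intrinsic ZYX: R = Rz(yaw) Ry(pitch) Rx(roll), sensor -> world
    R = Rotation.from_euler("ZYX", np.column_stack([yaw, pitch, roll])).as_matrix()
    omega_body = _body_rates(roll, pitch, roll_rate, pitch_rate, yaw_rate)
    a_world = _translation_accel(template.translation, v, v1, v2, total, amp_total)
    return t, R, omega_body, a_world


def simulate_trial(
    template: MovementTemplate,
    noise: NoiseModel,
    seed,
    fs: float = 100.0,
    mag_yaw_offset_deg: float = 0.0,
    participant_id: str = "P01",
    setting: str = "lab",
    trial_id: str = "",
    quality_label: str | None = None,
) -> ImuTrial:
    """Simulate one trial.  Deterministic given (template, noise, seed)."""
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    # fixed draw order keeps the stream aligned across template variants
    duration = float(
        np.clip(rng.normal(template.duration_mean, template.duration_sd), 1.0, 6.0)
    )
    amp = float(np.clip(1.0 + rng.normal(0.0, noise.amplitude_sd), 0.3, 2.0))
    warp = float(np.clip(rng.normal(0.0, noise.time_warp_sd), -0.25, 0.25))
    trunc_u = float(rng.uniform())

    t, R, omega_body, a_world = trial_kinematics(template, duration, fs, amp, warp)
    n = t.shape[0]

    # R^T v for every sample
    acc = np.einsum("tji,tj->ti", R, a_world + G_UP[None, :])
    gyro = omega_body.copy()
    yaw_off = math.radians(mag_yaw_offset_deg)
    m_world = Rotation.from_euler("Z", yaw_off).apply(M_EARTH)
    mag = np.einsum("tji,j->ti", R, m_world)

    dt = 1.0 / fs
    if noise.gyro_bias_walk > 0:
        gyro += np.cumsum(
            rng.normal(0.0, noise.gyro_bias_walk * math.sqrt(dt), (n, 3)), axis=0
        )
    if noise.acc_noise > 0:
        acc = acc + rng.normal(0.0, noise.acc_noise, (n, 3))
    if noise.gyro_noise > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_noise, (n, 3))
    if noise.mag_noise > 0:
        mag = mag + rng.normal(0.0, noise.mag_noise, (n, 3))

    if template.truncate_range is not None:
        lo, hi = template.truncate_range
        frac = lo + (hi - lo) * trunc_u
        n_keep = max(int(round(n * frac)), int(round(0.6 * fs)) + 1, 2)
        t, acc, gyro, mag = t[:n_keep], acc[:n_keep], gyro[:n_keep], mag[:n_keep]

    return ImuTrial(
        participant_id=participant_id,
        task_id=template.task_id,
        setting=setting,
        movement_type=template.movement_type,
        quality=quality_label if quality_label is not None else template.quality,
        t=t,
        acc=acc,
        gyro=gyro,
        mag=mag,
        fs_nominal=fs,
        trial_id=trial_id,
    )


# ---------------------------------------------------------------------------
# task templates and compensatory modifiers
# ---------------------------------------------------------------------------

def correct_template(task_id: int) -> MovementTemplate:
    """Nominal correct movement per task: reach-lift-place style motions
    with task-specific orientation and displacement signatures."""
    base = dict(task_id=task_id, movement_type="correct", quality=QUALITY_CORRECT)
    if task_id == 1:  # reach, lift object to a shelf, return
        return MovementTemplate(
            roll=AngleProfile(bump=0.25),
            pitch=AngleProfile(ramp=-0.5, bump=-0.2),
            yaw=AngleProfile(ramp=0.1),
            translation=TranslationProfile((0.25, 0.05, 0.35), 0.10),
            **base,
        )
    if task_id == 2:  # reach, bring object to the mouth, return
        return MovementTemplate(
            roll=AngleProfile(bump=0.45),
            pitch=AngleProfile(ramp=-0.9),
            yaw=AngleProfile(bump=0.15),
            translation=TranslationProfile((0.20, 0.0, 0.25), 0.15),
            **base,
        )
    if task_id == 3:  # grasp a tool, carry across the body midline
        return MovementTemplate(
            roll=AngleProfile(bump=0.3),
            pitch=AngleProfile(bump=-0.25),
            yaw=AngleProfile(ramp=-0.8),
            translation=TranslationProfile((0.15, -0.40, 0.05), 0.12),
            **base,
        )
    if task_id == 4:  # precision-grasp a small object, move it away
        return MovementTemplate(
            roll=AngleProfile(bump=0.15),
            pitch=AngleProfile(bump=-0.4),
            yaw=AngleProfile(ramp=0.2),
            translation=TranslationProfile((0.30, 0.0, 0.0), 0.18),
            **base,
        )
    raise ValueError(f"unknown task {task_id}")


def _scale_profile(p: AngleProfile, k: float) -> AngleProfile:
    return AngleProfile(offset=p.offset, ramp=p.ramp * k, bump=p.bump * k)


def apply_modifier(
    template: MovementTemplate, modifier: str, effect_scale: float = 1.0
) -> MovementTemplate:
    """Derive a compensatory variant from a correct template."""
    e = effect_scale
    tr = template.translation
    if modifier == "trunk_shoulder":
        # trunk flexion adds forward pitch; shoulder hike/abduction tilts the
        # wrist and raises the path while shortening the reach
        return replace(
            template,
            movement_type="trunk_shoulder",
            quality=QUALITY_INCORRECT,
            pitch=replace(template.pitch, bump=template.pitch.bump + 0.5 * e),
            roll=replace(template.roll, offset=template.roll.offset + 0.4 * e),
            translation=TranslationProfile(
                tuple(np.asarray(tr.displacement) * (1.0 - 0.3 * min(e, 1.0))),
                tr.peak_height + 0.08 * e,
            ),
        )
    if modifier == "compensatory_grip":
        # altered wrist extension at grasp plus a more ballistic transport
        return replace(
            template,
            movement_type="compensatory_grip",
            quality=QUALITY_INCORRECT,
            roll=replace(template.roll, ramp=template.roll.ramp + 0.5 * e),
            translation=TranslationProfile(
                tuple(np.asarray(tr.displacement) * (1.0 + 0.4 * e)),
                tr.peak_height,
            ),
            duration_mean=template.duration_mean * 0.9,
        )
    if modifier == "incomplete":
        # movement stops partway (object dropped / grasp failed)
        return replace(
            template,
            movement_type="incomplete",
            quality=QUALITY_INCORRECT,
            truncate_range=(0.4, 0.7),
        )
    if modifier == "nonparetic_assist":
        # the instrumented (paretic) wrist barely moves
        return replace(
            template,
            movement_type="nonparetic_assist",
            quality=QUALITY_INCORRECT,
            amplitude_scale=template.amplitude_scale * 0.15,
        )
    raise ValueError(f"unknown modifier {modifier!r}")


#: incorrect movement types present in the lab session, per task
DEFAULT_INCORRECT_TYPES = {
    1: ("trunk_shoulder", "compensatory_grip"),
    2: ("trunk_shoulder", "incomplete"),
    3: ("trunk_shoulder", "incomplete"),
    4: ("compensatory_grip", "incomplete"),
}


def task_templates(task_id: int, effect_scale: float = 1.0) -> list:
    """Correct template plus this task's compensatory variants."""
    correct = correct_template(task_id)
    return [correct] + [
        apply_modifier(correct, mod, effect_scale)
        for mod in DEFAULT_INCORRECT_TYPES[task_id]
    ]


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def _trial_seed(root: int, task: int, phase: int, index: int):
    return np.random.SeedSequence([int(root), int(task), int(phase), int(index)])


def simulate_participant(
    config: SyntheticConfig, seed: int
) -> tuple[Session, Session, pd.DataFrame]:
    """Generate one participant's lab and home sessions plus the home
    ground-truth table (columns: trial_id, task_id, movement_type,
    quality).  Home trials carry quality="unknown"; truth lives only in
    the table, as in the study the labels came from video review."""
    lab_trials = []
    home_trials = []
    truth_rows = []
    for task in config.tasks:
        templates = task_templates(task, config.effect_scale)
        correct, incorrect = templates[0], templates[1:]

        # lab: labeled trials per movement type
        idx = 0
        for tpl, n_trials in [(correct, config.lab_trials_correct)] + [
            (t, config.lab_trials_per_incorrect) for t in incorrect
        ]:
            for _ in range(n_trials):
                lab_trials.append(
                    simulate_trial(
                        tpl,
                        config.noise,
                        _trial_seed(seed, task, _PHASE_LAB, idx),
                        fs=config.fs,
                        mag_yaw_offset_deg=0.0,
                        participant_id=config.participant_id,
                        setting="lab",
                        trial_id=f"lab_t{task}_{tpl.movement_type}_{idx:02d}",
                    )
                )
                idx += 1

        # home: mixed qualities, truth kept separately
        n_home = config.home_trials_per_task
        n_correct = int(round(n_home * config.home_correct_fraction))
        incorrect_pool = list(incorrect)
        if config.home_only_type is not None:
            incorrect_pool.append(
                apply_modifier(correct, config.home_only_type, config.effect_scale)
            )
        schedule = [correct] * n_correct
        n_bad = n_home - n_correct
        n_home_only = 0
        if config.home_only_type is not None and n_bad:
            n_home_only = int(round(n_bad * config.home_only_fraction))
        base_bad = [t for t in incorrect_pool if t.movement_type != config.home_only_type]
        for k in range(n_bad - n_home_only):
            schedule.append(base_bad[k % len(base_bad)])
        schedule += [incorrect_pool[-1]] * n_home_only
        order = np.random.default_rng(
            _trial_seed(seed, task, _PHASE_MIX, 0)
        ).permutation(len(schedule))
        for i, pos in enumerate(order):
            tpl = schedule[pos]
            tid = f"home_t{task}_{i:03d}"
            home_trials.append(
                simulate_trial(
                    tpl,
                    config.noise,
                    _trial_seed(seed, task, _PHASE_HOME, i),
                    fs=config.fs,
                    mag_yaw_offset_deg=config.home_mag_yaw_offset_deg,
                    participant_id=config.participant_id,
                    setting="home",
                    trial_id=tid,
                    quality_label=QUALITY_UNKNOWN,
                )
            )
            home_trials[-1].movement_type = ""
            truth_rows.append(
                {
                    "trial_id": tid,
                    "task_id": task,
                    "movement_type": tpl.movement_type,
                    "quality": tpl.quality,
                }
            )

    lab = Session(config.participant_id, "lab", lab_trials)
    home = Session(config.participant_id, "home", home_trials)
    truth = pd.DataFrame(truth_rows)
    return lab, home, truth


def truth_mapping(truth: pd.DataFrame) -> dict:
    """trial_id -> (quality, movement_type) for score_session."""
    return {
        row.trial_id: (row.quality, row.movement_type)
        for row in truth.itertuples()
    }


# ---------------------------------------------------------------------------
# focused scenarios for validation studies
# ---------------------------------------------------------------------------

def gyro_only_templates() -> tuple[MovementTemplate, MovementTemplate]:
    """A correct/incorrect pair that differs *only* in the yaw trajectory:
    roll, pitch and translation are identical, so the gravity vector and
    linear acceleration carry no class signal (yaw leaves gravity
    untouched and there is no translation) — only the gyroscope does."""
    common = dict(
        task_id=1,
        roll=AngleProfile(bump=0.2),
        pitch=AngleProfile(bump=-0.15),
        translation=TranslationProfile((0.0, 0.0, 0.0), 0.0),
    )
    correct = MovementTemplate(
        movement_type="correct",
        quality=QUALITY_CORRECT,
        yaw=AngleProfile(bump=0.0),
        **common,
    )
    wiggle = MovementTemplate(
        movement_type="yaw_wiggle",
        quality=QUALITY_INCORRECT,
        yaw=AngleProfile(bump=0.9),
        **common,
    )
    return correct, wiggle


def gyro_only_participant(
    seed: int,
    n_lab_per_type: int = 6,
    n_home: int = 40,
    noise: NoiseModel = NoiseModel(),
    fs: float = 100.0,
    participant_id: str = "G01",
) -> tuple[Session, Session, pd.DataFrame]:
    """Single-task participant whose movement classes are separable only
    through the gyroscope channel."""
    correct, wiggle = gyro_only_templates()
    lab_trials = []
    for i in range(n_lab_per_type):
        for j, tpl in enumerate((correct, wiggle)):
            lab_trials.append(
                simulate_trial(
                    tpl,
                    noise,
                    _trial_seed(seed, 1, _PHASE_LAB, 2 * i + j),
                    fs=fs,
                    participant_id=participant_id,
                    setting="lab",
                    trial_id=f"lab_t1_{tpl.movement_type}_{i:02d}",
                )
            )
    home_trials = []
    truth_rows = []
    for i in range(n_home):
        tpl = correct if i % 2 == 0 else wiggle
        tid = f"home_t1_{i:03d}"
        home_trials.append(
            simulate_trial(
                tpl,
                noise,
                _trial_seed(seed, 1, _PHASE_HOME, i),
                fs=fs,
                mag_yaw_offset_deg=60.0,
                participant_id=participant_id,
                setting="home",
                trial_id=tid,
                quality_label=QUALITY_UNKNOWN,
            )
        )
        home_trials[-1].movement_type = ""
        truth_rows.append(
            {
                "trial_id": tid,
                "task_id": 1,
                "movement_type": tpl.movement_type,
                "quality": tpl.quality,
            }
        )
    return (
        Session(participant_id, "lab", lab_trials),
        Session(participant_id, "home", home_trials),
        pd.DataFrame(truth_rows),
    )


def static_template(roll: float, pitch: float, yaw: float) -> MovementTemplate:
    """Zero-motion template at a fixed orientation (filter validation)."""
    return MovementTemplate(
        task_id=0,
        movement_type="static",
        quality=QUALITY_CORRECT,
        roll=AngleProfile(offset=roll),
        pitch=AngleProfile(offset=pitch),
        yaw=AngleProfile(offset=yaw),
        duration_sd=0.0,
    )
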