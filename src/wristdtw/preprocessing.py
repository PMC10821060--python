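"""Orientation/gravity estimation and channel-matrix assembly.

The wrist sensor's accelerometer reads specific force: gravity plus
movement-induced linear acceleration, both expressed in the sensor frame.
A six-axis (accelerometer + gyroscope) orientation filter separates the
two: gyroscope integration propagates orientation between samples and the
accelerometer direction corrects the tilt drift.  The magnetometer is
never fused — yaw is unobservable but gravity does not depend on it.

The filter here is an error-state (multiplicative) Kalman filter on the
3-dof attitude error: nominal state is a unit quaternion, the covariance
lives on the tangent space.  The accelerometer measurement noise is
inflated when the specific-force magnitude departs from 1 g, which
de-weights the correction during vigorous movement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import ImuTrial, STANDARD_GRAVITY

logger = logging.getLogger(__name__)

# canonical channel-group order used everywhere downstream
CHANNEL_GROUPS = ("lin_acc", "grav", "gyro", "mag")
_AXES = ("x", "y", "z")


class DegenerateInputError(ValueError):
    """Orientation unobservable (e.g. all-zero accelerometer)."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterParams:
    """Six-axis filter noise settings.

    gyro_noise: rad/s (process noise driving attitude error)
    acc_noise: unitless sd on the normalized gravity-direction measurement
    dynamic_gain: extra measurement variance per (|f|-g)^2, de-weighting
        the accelerometer during high dynamics
    """

    gyro_noise: float = 0.02
    acc_noise: float = 0.05
    dynamic_gain: float = 2.0


@dataclass
class OrientationSeries:
    """Per-sample sensor-to-world unit quaternions (w, x, y, z)."""

    q: np.ndarray  # (T, 4)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.q, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("quaternions must be unit-norm to 1e-6")

    def rotation_matrices(self) -> np.ndarray:
        return np.stack([_quat_to_matrix(qi) for qi in self.q])


@dataclass
class ChannelMatrix:
    """T x C matrix of selected sensor channels, column labels attached."""

    values: np.ndarray
    channel_names: tuple
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match column count")
        if self.values.shape[1] not in (3, 6, 9, 12):
            raise ValueError("channel count must be one of 3, 6, 9, 12")
        if not np.isfinite(self.values).all():
            raise ValueError("channel matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AxisScales:
    """Per-channel standard deviations used for normalization."""

    sigma: np.ndarray
    channel_names: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("scales must be strictly positive")
        if self.sigma.shape[0] != len(self.channel_names):
            raise ValueError("one scale per channel required")

    def subset(self, names: Sequence[str]) -> "AxisScales":
        idx = [self.channel_names.index(n) for n in names]
        return AxisScales(self.sigma[idx], tuple(names))


# ---------------------------------------------------------------------------
# quaternion helpers (w, x, y, z convention; q maps sensor -> world)
# ---------------------------------------------------------------------------

def _quat_mult(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _quat_from_rotvec(v):
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]) / np.sqrt(
            1.0 + 0.25 * angle * angle
        )
    axis = v / angle
    s = np.sin(0.5 * angle)
    return np.array([np.cos(0.5 * angle), s * axis[0], s * axis[1], s * axis[2]])


def _quat_to_matrix(q):
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _quat_from_two_vectors(u, v):
    """Shortest-arc quaternion rotating unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c < -1.0 + 1e-12:
        # antipodal: rotate 180 deg about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        return np.array([0.0, axis[0], axis[1], axis[2]])
    axis = np.cross(u, v)
    q = np.array([1.0 + c, axis[0], axis[1], axis[2]])
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# gravity estimation
# ---------------------------------------------------------------------------

def estimate_gravity(
    trial: ImuTrial, params: FilterParams | None = None
) -> tuple[OrientationSeries, np.ndarray, np.ndarray]:
    """Estimate orientation and split the accelerometer into gravity and
    linear acceleration.

    Returns ``(orientation, gravity, lin_acc)`` where ``gravity`` is the
    gravity component expressed in the sensor frame (magnitude fixed at
    standard gravity) and ``lin_acc = acc - gravity`` sample-wise, so the
    raw accelerometer stream reconstructs exactly.
    """
    params = params or FilterParams()
    if trial.duration < 0.5:
        raise DegenerateInputError("trial shorter than 0.5 s")
    acc = trial.acc
    gyro = trial.gyro
    t = trial.t
    n = trial.n_samples

    a0 = acc[0]
    if np.linalg.norm(a0) < 1e-6:
        raise DegenerateInputError("all-zero accelerometer: orientation unobservable")

    ez = np.array([0.0, 0.0, 1.0])
    # initialize tilt from the first sample: world +z maps to the measured
    # specific-force direction in the sensor frame (zero yaw)
    g_dir0 = a0 / np.linalg.norm(a0)
    # q maps sensor->world; we need R^T ez = g_dir0, i.e. R g_dir0 = ez
    q = _quat_from_two_vectors(g_dir0, ez)

    P = np.eye(3) * 0.1  # attitude-error covariance (rad^2)
    Q = np.eye(3) * params.gyro_noise**2
    quats = np.empty((n, 4))
    quats[0] = q

    for k in range(1, n):
        dt = t[k] - t[k - 1]
        # propagate: body-frame gyro increment on the right
        q = _quat_mult(q, _quat_from_rotvec(gyro[k] * dt))
        q = q / np.linalg.norm(q)
        P = P + Q * dt

        a = acc[k]
        na = np.linalg.norm(a)
        if na > 1e-6:
            z = a / na
            R = _quat_to_matrix(q)
            h = R.T @ ez  # predicted gravity direction in sensor frame
            y = z - h
            H = np.array(
                [
                    [0.0, -h[2], h[1]],
                    [h[2], 0.0, -h[0]],
                    [-h[1], h[0], 0.0],
                ]
            )
            dyn = (na - STANDARD_GRAVITY) / STANDARD_GRAVITY
            r_var = params.acc_noise**2 + params.dynamic_gain * dyn * dyn
            S = H @ P @ H.T + np.eye(3) * r_var
            K = P @ H.T @ np.linalg.inv(S)
            dtheta = K @ y
            # error is defined on the sensor side: R_true = R_hat Exp(dtheta)
            q = _quat_mult(q, _quat_from_rotvec(dtheta))
            q = q / np.linalg.norm(q)
            P = (np.eye(3) - K @ H) @ P
        quats[k] = q

    orient = OrientationSeries(quats)
    Rs = orient.rotation_matrices()
    gravity = np.einsum("tji,j->ti", Rs, ez) * STANDARD_GRAVITY
    lin_acc = acc - gravity
    return orient, gravity, lin_acc


def lowpass_gravity(trial: ImuTrial, cutoff_hz: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Accelerometer-only gravity estimate: zero-phase 2nd-order Butterworth
    low-pass per axis.  Used by the acceleration-only ablation, emulating a
    logger that records no gyroscope."""
    from scipy.signal import butter, filtfilt

    fs = trial.fs_nominal
    b, a = butter(2, cutoff_hz / (fs / 2.0), btype="low")
    padlen = min(3 * max(len(b), len(a)), trial.n_samples - 1)
    gravity = np.column_stack(
        [filtfilt(b, a, trial.acc[:, k], padlen=padlen) for k in range(3)]
    )
    # keep the gravity magnitude physical; the low-pass preserves direction
    norms = np.linalg.norm(gravity, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    gravity = gravity / norms * STANDARD_GRAVITY
    return gravity, trial.acc - gravity


# ---------------------------------------------------------------------------
# channel assembly and normalization
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedTrial:
    """All derivable channel streams of one trial, computed once."""

    trial: ImuTrial
    streams: dict  # group name -> (T, 3) array
    fs: float

    @property
    def quality(self) -> str:
        return self.trial.quality

    @property
    def movement_type(self) -> str:
        return self.trial.movement_type

    @property
    def task_id(self) -> int:
        return self.trial.task_id


def preprocess_trial(
    trial: ImuTrial,
    params: FilterParams | None = None,
    gravity_estimator: str = "kalman",
) -> PreprocessedTrial:
    """Run gravity estimation once and stash every channel group."""
    if gravity_estimator == "kalman":
        _, gravity, lin_acc = estimate_gravity(trial, params)
    elif gravity_estimator == "lowpass":
        gravity, lin_acc = lowpass_gravity(trial)
    else:
        raise ConfigurationError(f"unknown gravity estimator {gravity_estimator!r}")
    streams = {
        "lin_acc": lin_acc,
        "grav": gravity,
        "gyro": trial.gyro,
        "mag": trial.mag,
    }
    return PreprocessedTrial(trial=trial, streams=streams, fs=trial.fs_nominal)


def channel_names(groups: Sequence[str]) -> tuple:
    ordered = [g for g in CHANNEL_GROUPS if g in groups]
    return tuple(f"{g}_{ax}" for g in ordered for ax in _AXES)


def assemble_channels(pre, method) -> ChannelMatrix:
    """Stack the selected channel groups in canonical order.

    ``pre`` is a PreprocessedTrial (or an ImuTrial, preprocessed on the
    fly); ``method`` anything with a ``channels`` attribute or a plain
    sequence of group names.
    """
    groups = getattr(method, "channels", method)
    groups = tuple(groups)
    if not groups:
        raise ConfigurationError("empty channel set")
    unknown = set(groups) - set(CHANNEL_GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown channel groups {sorted(unknown)}")
    if isinstance(pre, ImuTrial):
        pre = preprocess_trial(pre)
    ordered = [g for g in CHANNEL_GROUPS if g in groups]
    values = np.hstack([pre.streams[g] for g in ordered])
    return ChannelMatrix(values=values, channel_names=channel_names(ordered), fs=pre.fs)


def compute_axis_scales(matrices: Sequence[ChannelMatrix]) -> AxisScales:
    """Per-channel sample (n-1) standard deviation over the concatenation
    of the given (lab) matrices.  Zero scales fall back to 1 with a
    warning so constant channels pass through unscaled."""
    if not matrices:
        raise ValueError("no matrices given")
    names = matrices[0].channel_names
    for m in matrices[1:]:
        if m.channel_names != names:
            raise ValueError("matrices have mismatched channels")
    stacked = np.vstack([m.values for m in matrices])
    if stacked.shape[0] < 2:
        raise ValueError("need >=2 total samples per channel")
    sigma = stacked.std(axis=0, ddof=1)
    zero = sigma == 0
    if zero.any():
        warnings.warn(
            f"constant channels {[names[i] for i in np.where(zero)[0]]}: "
            "scale set to 1",
            stacklevel=2,
        )
        sigma = np.where(zero, 1.0, sigma)
    return AxisScales(sigma=sigma, channel_names=names)


def normalize(matrix: ChannelMatrix, scales: AxisScales) -> ChannelMatrix:
    """Divide each column by its scale (no centering)."""
    if scales.channel_names != matrix.channel_names:
        raise ValueError("scales do not match matrix channels")
    return ChannelMatrix(
        values=matrix.values / scales.sigma[None, :],
        channel_names=matrix.channel_names,
        fs=matrix.fs,
    )
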