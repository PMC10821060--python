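"""Trial and session I/O.

On-disk conventions
-------------------
* One CSV file per trial with header ``t,ax,ay,az,gx,gy,gz,mx,my,mz``
  (time in seconds since trial start, then accelerometer, gyroscope and
  magnetometer triplets in the sensor frame).
* A JSON session manifest listing the trial files together with their
  metadata (participant, task, lab/home setting, movement type, quality).

Internally everything is SI: accelerometer in m/s^2, gyroscope in rad/s,
magnetometer in microtesla.  Source units are declared at read time
because wrist-logger exports vary (accelerometer counts in g are common).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STANDARD_GRAVITY = 9.80665  # m/s^2

TRIAL_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]

QUALITY_CORRECT = "correct"
QUALITY_INCORRECT = "incorrect"
QUALITY_UNKNOWN = "unknown"
QUALITIES = (QUALITY_CORRECT, QUALITY_INCORRECT, QUALITY_UNKNOWN)


class FormatError(ValueError):
    """Trial file does not match the expected column layout."""


class DataError(ValueError):
    """Trial contents violate a data invariant (timestamps, length...)."""


class ValidationError(ValueError):
    """Session-level metadata inconsistency."""


@dataclass(frozen=True)
class UnitsConfig:
    """Declared source units of a trial file.

    ``acc``: ``"g"`` or ``"m/s2"``; ``gyro``: ``"deg/s"`` or ``"rad/s"``;
    magnetometer is always microtesla.
    """

    acc: str = "m/s2"
    gyro: str = "rad/s"

    def acc_factor(self) -> float:
        if self.acc == "g":
            return STANDARD_GRAVITY
        if self.acc == "m/s2":
            return 1.0
        raise FormatError(f"unknown accelerometer unit {self.acc!r}")

    def gyro_factor(self) -> float:
        if self.gyro == "deg/s":
            return math.pi / 180.0
        if self.gyro == "rad/s":
            return 1.0
        raise FormatError(f"unknown gyroscope unit {self.gyro!r}")


@dataclass
class ImuTrial:
    """One segmented task repetition from the wrist sensor.

    Samples are stored as arrays (``t`` shape (N,), ``acc``/``gyro``/``mag``
    shape (N, 3)) rather than per-sample records; ``samples`` offers the
    record view when needed.
    """

    participant_id: str
    task_id: int
    setting: str  # "lab" | "home"
    movement_type: str
    quality: str  # "correct" | "incorrect" | "unknown"
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    fs_nominal: float = 100.0
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise DataError(f"trial {self.trial_id or '<anon>'}: fewer than 2 samples")
        for name, arr in (("acc", self.acc), ("gyro", self.gyro), ("mag", self.mag)):
            if arr.shape != (n, 3):
                raise FormatError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            if not np.isfinite(arr).all():
                raise DataError(f"{name} contains non-finite values")
        if not np.isfinite(self.t).all() or self.t[0] < 0:
            raise DataError("timestamps must be finite and nonnegative")
        if np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.setting not in ("lab", "home"):
            raise ValidationError(f"setting must be lab|home, got {self.setting!r}")
        if self.quality not in QUALITIES:
            raise ValidationError(f"unknown quality label {self.quality!r}")
        if self.quality != QUALITY_UNKNOWN and not self.movement_type:
            raise ValidationError("labeled trial needs a movement_type")
        med_dt = float(np.median(np.diff(self.t)))
        if abs(med_dt - 1.0 / self.fs_nominal) > 0.2 / self.fs_nominal:
            raise DataError(
                f"median sampling interval {med_dt:.4f}s deviates >20% from "
                f"nominal {1.0 / self.fs_nominal:.4f}s; resample first"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def samples(self) -> Iterable[tuple]:
        """Record view: yields (t, acc, gyro, mag) per sample."""
        for i in range(self.n_samples):
            yield (self.t[i], self.acc[i], self.gyro[i], self.mag[i])

    def with_labels(self, **kw) -> "ImuTrial":
        return replace(self, **kw)


@dataclass
class Session:
    """All trials of one participant in one setting, grouped by task."""

    participant_id: str
    setting: str
    trials: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for tr in self.trials:
            if tr.participant_id != self.participant_id:
                raise ValidationError(
                    f"trial {tr.trial_id} participant {tr.participant_id!r} "
                    f"does not match session {self.participant_id!r}"
                )
            if tr.setting != self.setting:
                raise ValidationError(
                    f"trial {tr.trial_id} setting {tr.setting!r} does not "
                    f"match session {self.setting!r}"
                )
            if self.setting == "lab" and tr.quality == QUALITY_UNKNOWN:
                raise ValidationError(
                    f"lab trial {tr.trial_id} must carry a quality label"
                )

    @property
    def task_ids(self) -> list:
        return sorted({tr.task_id for tr in self.trials})

    def by_task(self, task_id) -> list:
        return [tr for tr in self.trials if tr.task_id == task_id]

    def validate_lab_reference(self) -> None:
        """A usable lab reference set needs, per task, >=2 movement types
        with >=2 trials each, covering both quality classes."""
        if self.setting != "lab":
            raise ValidationError("reference validation applies to lab sessions")
        for task in self.task_ids:
            trials = self.by_task(task)
            types: dict = {}
            for tr in trials:
                types.setdefault(tr.movement_type, []).append(tr)
            if len(types) < 2 or any(len(v) < 2 for v in types.values()):
                raise ValidationError(
                    f"task {task}: need >=2 movement types with >=2 trials each"
                )
            quals = {tr.quality for tr in trials}
            if not {QUALITY_CORRECT, QUALITY_INCORRECT} <= quals:
                raise ValidationError(
                    f"task {task}: need at least one correct and one incorrect type"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_trial(
    path,
    units: UnitsConfig | None = None,
    *,
    participant_id: str = "",
    task_id: int = 0,
    setting: str = "home",
    movement_type: str = "",
    quality: str = QUALITY_UNKNOWN,
    fs_nominal: float = 100.0,
    trial_id: str = "",
    resample: bool = True,
) -> ImuTrial:
    """Read one trial CSV and convert channels to internal SI units."""
    units = units or UnitsConfig()
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise DataError(f"{path}: fewer than 2 rows")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: non-monotone timestamps")
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float) * units.acc_factor()
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * units.gyro_factor()
    mag = df[["mx", "my", "mz"]].to_numpy(dtype=float)
    if resample:
        t, acc, gyro, mag = _resample_uniform(t, acc, gyro, mag, fs_nominal)
    return ImuTrial(
        participant_id=participant_id,
        task_id=task_id,
        setting=setting,
        movement_type=movement_type,
        quality=quality,
        t=t,
        acc=acc,
        gyro=gyro,
        mag=mag,
        fs_nominal=fs_nominal,
        trial_id=trial_id or Path(path).stem,
    )


def _resample_uniform(t, acc, gyro, mag, fs):
    """Linearly resample onto a uniform grid at fs if the stream drifts
    more than 2% from nominal; otherwise return unchanged."""
    dt = np.diff(t)
    if abs(float(np.median(dt)) - 1.0 / fs) <= 0.02 / fs and dt.max() - dt.min() < 0.5 / fs:
        return t, acc, gyro, mag
    t_new = np.arange(t[0], t[-1] + 1e-12, 1.0 / fs)
    if t_new.shape[0] < 2:
        t_new = np.array([t[0], t[-1]])

    def interp(block):
        return np.column_stack([np.interp(t_new, t, block[:, k]) for k in range(3)])

    return t_new, interp(acc), interp(gyro), interp(mag)


def write_trial(trial: ImuTrial, path) -> None:
    """Write a trial CSV in internal units (round-trips with read_trial
    under the default UnitsConfig)."""
    df = pd.DataFrame(
        np.column_stack([trial.t, trial.acc, trial.gyro, trial.mag]),
        columns=TRIAL_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_session(manifest_path, units: UnitsConfig | None = None) -> Session:
    """Load a session from a JSON manifest.

    Manifest schema::

        {"participant_id": ..., "setting": "lab"|"home", "fs_nominal": 100,
         "units": {"acc": "m/s2", "gyro": "rad/s"},
         "trials": [{"file": ..., "task_id": ..., "movement_type": ...,
                     "quality": "correct"|"incorrect"|"unknown"}, ...]}
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    units = units or UnitsConfig(**man.get("units", {}))
    fs = float(man.get("fs_nominal", 100.0))
    setting = man["setting"]
    pid = man["participant_id"]
    trials = []
    for i, entry in enumerate(man["trials"]):
        quality = entry.get("quality", QUALITY_UNKNOWN)
        if setting == "lab" and quality == QUALITY_UNKNOWN:
            raise ValidationError(f"lab trial {entry['file']} lacks a quality label")
        trials.append(
            read_trial(
                manifest_path.parent / entry["file"],
                units,
                participant_id=entry.get("participant_id", pid),
                task_id=int(entry["task_id"]),
                setting=setting,
                movement_type=entry.get("movement_type", ""),
                quality=quality,
                fs_nominal=fs,
                trial_id=entry.get("trial_id", f"{setting}_{i:04d}"),
            )
        )
    return Session(participant_id=pid, setting=setting, trials=trials)


def write_session(session: Session, directory, *, truth: pd.DataFrame | None = None) -> Path:
    """Write all trials plus the manifest under ``directory``; returns the
    manifest path.  ``truth`` (home ground truth) is written alongside."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in session.trials:
        fname = f"{tr.trial_id}.csv"
        write_trial(tr, directory / fname)
        entries.append(
            {
                "file": fname,
                "trial_id": tr.trial_id,
                "task_id": tr.task_id,
                "movement_type": tr.movement_type,
                "quality": tr.quality,
            }
        )
    man = {
        "participant_id": session.participant_id,
        "setting": session.setting,
        "fs_nominal": session.trials[0].fs_nominal if session.trials else 100.0,
        "units": {"acc": "m/s2", "gyro": "rad/s"},
        "trials": entries,
    }
    man_path = directory / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(man, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if truth is not None:
        truth.to_csv(directory / "truth.csv", index=False)
    return man_path


def write_report(report, path) -> None:
    """Serialize a QualityReport as JSON plus a per-trial prediction CSV.

    ``path`` is the JSON destination; the CSV goes next to it with the
    suffix ``_predictions.csv``.
    """
    from .classification import QualityReport  # local import avoids a cycle

    if not isinstance(report, QualityReport):
        raise TypeError("write_report expects a QualityReport")
    if report.overall.total == 0:
        raise ValidationError("nothing to report: no scored trials")
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    report.predictions_frame().to_csv(
        path.with_name(path.stem + "_predictions.csv"), index=False
    )


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
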