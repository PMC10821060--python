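"""Home-trial classification and reporting metrics.

Each home trial is classified by 1-nearest-neighbor against the
participant's own lab reference trials of the same task: projected DTW
distances (home trial as test) to every lab trial are computed under the
selected method, and the quality label of the closest lab trial is
assigned.  Reports follow the study design: an overall confusion matrix,
per-task matrices, accuracy and F1 (positive class = correct movement),
and per-movement-type sensitivity for the incorrect trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    QUALITY_CORRECT,
    QUALITY_INCORRECT,
    QUALITY_UNKNOWN,
    Session,
    ValidationError,
)
from .dtw_core import InfeasibleWindowError, dtw_align
from .method_selection import (
    MethodConfig,
    SelectionResult,
    default_grid,
    group_lab_by_task,
    lab_distance_matrix,
    select_method,
)
from .preprocessing import (
    AxisScales,
    FilterParams,
    PreprocessedTrial,
    assemble_channels,
    compute_axis_scales,
    normalize,
    preprocess_trial,
)

logger = logging.getLogger(__name__)


@dataclass
class TrialPrediction:
    trial_id: str
    task_id: int
    predicted_quality: str | None  # None when unclassifiable
    nearest_lab_trial: str | None
    nearest_distance: float | None
    distances: np.ndarray | None
    true_quality: str = QUALITY_UNKNOWN
    true_movement_type: str = ""

    @property
    def classifiable(self) -> bool:
        return self.predicted_quality is not None


@dataclass
class ConfusionMatrix:
    """2x2 counts; positive class = correct movement."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")

    def add(self, truth: str, pred: str) -> None:
        if truth == QUALITY_CORRECT:
            if pred == QUALITY_CORRECT:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if pred == QUALITY_CORRECT:
                self.fp += 1
            else:
                self.tn += 1

    def as_list(self) -> list:
        return [[self.tp, self.fn], [self.fp, self.tn]]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


@dataclass
class QualityReport:
    overall: ConfusionMatrix
    per_task: dict  # task_id -> ConfusionMatrix
    sensitivity_by_type: dict  # movement_type -> (hits, total)
    predictions: list
    method: MethodConfig | None = None
    ablation: str = "all_channels"  # or "acceleration_only"
    n_unclassifiable: int = 0

    @property
    def accuracy(self) -> float:
        return self.overall.accuracy

    @property
    def f1(self) -> float:
        return self.overall.f1

    def to_dict(self) -> dict:
        return {
            "ablation": self.ablation,
            "method": self.method.label() if self.method else None,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "n_scored": self.overall.total,
            "n_unclassifiable": self.n_unclassifiable,
            "overall_matrix": self.overall.as_list(),
            "per_task": {
                str(task): {
                    "matrix": cm.as_list(),
                    "accuracy": cm.accuracy,
                    "f1": cm.f1,
                }
                for task, cm in sorted(self.per_task.items())
            },
            "sensitivity_by_type": {
                mt: {"hits": h, "total": n, "sensitivity": h / n if n else None}
                for mt, (h, n) in sorted(self.sensitivity_by_type.items())
            },
        }

    def predictions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial_id": p.trial_id,
                "task_id": p.task_id,
                "predicted_quality": p.predicted_quality or "unclassifiable",
                "true_quality": p.true_quality,
                "true_movement_type": p.true_movement_type,
                "nearest_lab_trial": p.nearest_lab_trial or "",
                "nearest_distance": p.nearest_distance,
            }
            for p in self.predictions
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_trial(
    home_pre: PreprocessedTrial,
    lab_pres: Sequence[PreprocessedTrial],
    method: MethodConfig,
    scales: AxisScales | None,
) -> TrialPrediction:
    """1-NN classification of one preprocessed home trial.

    ``scales`` must be the lab-derived axis scales when the method
    normalizes (home trials never contribute to the scales).  Distance
    ties go to the lab trial earliest in session order.  If every lab
    comparison is infeasible under the window, the trial is flagged
    unclassifiable instead of silently mis-scored.
    """
    if not lab_pres:
        raise ValueError("empty lab reference set")
    test = assemble_channels(home_pre, method)
    if method.normalize:
        if scales is None:
            raise ValueError("normalizing method needs lab-derived scales")
        test = normalize(test, scales)
    dists = np.full(len(lab_pres), np.nan)
    for k, lab in enumerate(lab_pres):
        ref = assemble_channels(lab, method)
        if method.normalize:
            ref = normalize(ref, scales)
        try:
            dists[k] = dtw_align(test, ref, method.window_w).projected_distance
        except InfeasibleWindowError:
            continue
    trial = home_pre.trial
    if np.isnan(dists).all():
        return TrialPrediction(
            trial_id=trial.trial_id,
            task_id=trial.task_id,
            predicted_quality=None,
            nearest_lab_trial=None,
            nearest_distance=None,
            distances=dists,
            true_quality=trial.quality,
            true_movement_type=trial.movement_type,
        )
    best = int(np.nanargmin(dists))  # first minimum = earliest lab trial
    return TrialPrediction(
        trial_id=trial.trial_id,
        task_id=trial.task_id,
        predicted_quality=lab_pres[best].quality,
        nearest_lab_trial=lab_pres[best].trial.trial_id,
        nearest_distance=float(dists[best]),
        distances=dists,
        true_quality=trial.quality,
        true_movement_type=trial.movement_type,
    )


def classify_session(
    home: Session,
    lab_tasks: Mapping,
    method: MethodConfig,
    filter_params: FilterParams | None = None,
    gravity_estimator: str = "kalman",
) -> list:
    """Classify every home trial against the lab references of its task."""
    predictions = []
    scales_by_task: dict = {}
    for task_id, pres in lab_tasks.items():
        if method.normalize:
            mats = [assemble_channels(p, method) for p in pres]
            scales_by_task[task_id] = compute_axis_scales(mats)
        else:
            scales_by_task[task_id] = None
    for tr in home.trials:
        if tr.task_id not in lab_tasks:
            raise ValidationError(f"no lab references for task {tr.task_id}")
        home_pre = preprocess_trial(tr, filter_params, gravity_estimator)
        predictions.append(
            classify_trial(
                home_pre, lab_tasks[tr.task_id], method, scales_by_task[tr.task_id]
            )
        )
    return predictions


def score_session(
    predictions: Sequence[TrialPrediction],
    truth: Mapping | None = None,
    method: MethodConfig | None = None,
    ablation: str = "all_channels",
) -> QualityReport:
    """Build the quality report from predictions and ground truth.

    ``truth`` maps trial_id -> quality (and optionally movement type via a
    (quality, movement_type) tuple); when omitted, the labels carried on
    the trials are used.  Unclassifiable trials are counted separately and
    excluded from the matrices.
    """
    overall = ConfusionMatrix()
    per_task: dict = {}
    sens: dict = {}
    n_unclassifiable = 0
    for p in predictions:
        true_q = p.true_quality
        true_mt = p.true_movement_type
        if truth is not None and p.trial_id in truth:
            entry = truth[p.trial_id]
            if isinstance(entry, tuple):
                true_q, true_mt = entry
            else:
                true_q = entry
        if true_q == QUALITY_UNKNOWN:
            raise ValidationError(f"trial {p.trial_id}: ground truth missing")
        p.true_quality = true_q
        p.true_movement_type = true_mt
        if not p.classifiable:
            n_unclassifiable += 1
            continue
        overall.add(true_q, p.predicted_quality)
        per_task.setdefault(p.task_id, ConfusionMatrix()).add(
            true_q, p.predicted_quality
        )
        if true_q == QUALITY_INCORRECT:
            h, n = sens.get(true_mt, (0, 0))
            sens[true_mt] = (h + (p.predicted_quality == QUALITY_INCORRECT), n + 1)
    return QualityReport(
        overall=overall,
        per_task=per_task,
        sensitivity_by_type=sens,
        predictions=list(predictions),
        method=method,
        ablation=ablation,
        n_unclassifiable=n_unclassifiable,
    )


# ---------------------------------------------------------------------------
# end-to-end runs and the acceleration-only ablation
# ---------------------------------------------------------------------------

def run_participant(
    lab: Session,
    home: Session,
    grid: Sequence[MethodConfig] | None = None,
    alpha: float = 0.05,
    filter_params: FilterParams | None = None,
    gravity_estimator: str = "kalman",
    ablation: str = "all_channels",
    truth: Mapping | None = None,
) -> tuple[SelectionResult, QualityReport]:
    """select -> classify -> score for one participant."""
    grid = list(grid) if grid is not None else default_grid()
    lab_tasks = group_lab_by_task(lab, filter_params, gravity_estimator)
    selection = select_method(lab_tasks, grid, alpha=alpha)
    preds = classify_session(
        home, lab_tasks, selection.selected, filter_params, gravity_estimator
    )
    report = score_session(preds, truth, method=selection.selected, ablation=ablation)
    return selection, report


def ablation_compare(
    lab: Session,
    home: Session,
    grid: Sequence[MethodConfig] | None = None,
    alpha: float = 0.05,
    filter_params: FilterParams | None = None,
    truth: Mapping | None = None,
) -> tuple[QualityReport, QualityReport]:
    """All-channel pipeline vs an acceleration-only device.

    The ablation restricts the method grid to channel groups derivable
    from the accelerometer alone ({lin_acc, grav}) and swaps the six-axis
    gravity estimator for an accelerometer-only low-pass estimator — the
    scenario of a logger that records no gyroscope to save battery.
    Selection is re-run inside the restricted subspace.
    """
    grid = list(grid) if grid is not None else default_grid()
    _, full_report = run_participant(
        lab, home, grid, alpha, filter_params, "kalman", "all_channels", truth
    )
    acc_subsets = [
        m.channels
        for m in grid
        if set(m.channels) <= {"lin_acc", "grav"}
    ]
    acc_grid = [m for m in grid if set(m.channels) <= {"lin_acc", "grav"}]
    if not acc_grid:
        windows = sorted({m.window_w for m in grid})
        acc_grid = default_grid(
            windows=windows,
            channel_subsets=[("lin_acc",), ("grav",), ("lin_acc", "grav")],
        )
    _, acc_report = run_participant(
        lab, home, acc_grid, alpha, filter_params, "lowpass", "acceleration_only", truth
    )
    return full_report, acc_report
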