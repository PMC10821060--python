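"""Participant-specific method selection.

The pipeline explores a grid of analysis methods — which channel groups
to feed DTW (linear acceleration, gravity vector, gyroscope, optionally
magnetometer), whether to normalize each axis by its lab standard
deviation, and the warping-window size — and picks, per participant, the
method that best separates their own movement qualities on the lab data:

1.  *Discernability.*  For every unordered pair of movement types with
    opposite quality labels, projected DTW distances within each type
    (self-pairs excluded, both types pooled) are compared to distances
    between the types (both directions) with a one-sided Welch t-test
    (alternative: within < between).  The max p over pairs — and, when a
    session spans several tasks, over tasks — summarizes the method.
2.  *Candidate set.*  Methods with p_max below alpha (default 0.05); if
    none pass, the argmin-p methods.
3.  *Leave-one-trial-out.*  Among candidates, keep those with the highest
    LOTO 1-nearest-neighbor accuracy on the lab trials.
4.  *Preference rule.*  Remaining ties go to linear acceleration +
    gravity + gyroscope with normalization, then the longer warping
    window, then the canonical channel-set order.

Every step is recorded in the selection trace; given the same session and
grid the selection is fully deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import QUALITY_CORRECT, QUALITY_INCORRECT, Session
from .dtw_core import InfeasibleWindowError, pairwise_distances
from .preprocessing import (
    CHANNEL_GROUPS,
    AxisScales,
    ConfigurationError,
    FilterParams,
    PreprocessedTrial,
    assemble_channels,
    compute_axis_scales,
    normalize,
    preprocess_trial,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (50, 100, 200, 300, 400)  # 0.5x .. 4x of fs = 100 Hz
PREFERRED_CHANNELS = ("lin_acc", "grav", "gyro")


@dataclass(frozen=True)
class MethodConfig:
    """One point in the method grid."""

    channels: tuple  # subset of CHANNEL_GROUPS, canonical order
    normalize: bool
    window_w: int

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigurationError("channels must be nonempty")
        unknown = set(self.channels) - set(CHANNEL_GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown channels {sorted(unknown)}")
        ordered = tuple(g for g in CHANNEL_GROUPS if g in self.channels)
        object.__setattr__(self, "channels", ordered)

    def label(self) -> str:
        norm = "norm" if self.normalize else "raw"
        return f"{'+'.join(self.channels)}|{norm}|w{self.window_w}"


def default_grid(
    windows: Sequence[int] = DEFAULT_WINDOWS,
    include_mag: bool = False,
    normalize_options: Sequence[bool] = (True, False),
    channel_subsets: Sequence[tuple] | None = None,
) -> list:
    """All nonempty subsets of {lin_acc, grav, gyro} (plus magnetometer
    combinations when include_mag) crossed with normalization and window
    options.  Magnetometer is off by default: its reading tracks heading
    relative to the earth field, which differs between lab and home."""
    if channel_subsets is None:
        base = ("lin_acc", "grav", "gyro") + (("mag",) if include_mag else ())
        channel_subsets = [
            combo
            for r in range(1, len(base) + 1)
            for combo in itertools.combinations(base, r)
        ]
    return [
        MethodConfig(channels=tuple(ch), normalize=nrm, window_w=int(w))
        for ch in channel_subsets
        for nrm in normalize_options
        for w in windows
    ]


@dataclass
class MethodRecord:
    method: MethodConfig
    p_max: float | None
    feasible: bool
    loto_accuracy: float | None

    def to_dict(self) -> dict:
        return {
            "method": self.method.label(),
            "channels": list(self.method.channels),
            "normalize": self.method.normalize,
            "window_w": self.method.window_w,
            "p_max": self.p_max,
            "feasible": self.feasible,
            "loto_accuracy": self.loto_accuracy,
        }


@dataclass
class SelectionResult:
    records: list
    selected: MethodConfig
    selection_trace: list

    def to_dict(self) -> dict:
        return {
            "selected": {
                "channels": list(self.selected.channels),
                "normalize": self.selected.normalize,
                "window_w": self.selected.window_w,
            },
            "records": [r.to_dict() for r in self.records],
            "trace": list(self.selection_trace),
        }


# ---------------------------------------------------------------------------
# distance plumbing
# ---------------------------------------------------------------------------

def _group_by_type(trials: Sequence[PreprocessedTrial]) -> dict:
    groups: dict = {}
    for idx, tr in enumerate(trials):
        groups.setdefault(tr.movement_type, []).append(idx)
    return groups


def lab_distance_matrix(
    pres: Sequence[PreprocessedTrial], method: MethodConfig
) -> tuple[np.ndarray, AxisScales | None]:
    """Directed projected-distance matrix among lab trials under a method.

    Normalization scales come from the concatenation of these same lab
    trials (the participant's reference data); the scales are returned so
    home trials can be normalized identically."""
    mats = [assemble_channels(p, method) for p in pres]
    scales = None
    if method.normalize:
        scales = compute_axis_scales(mats)
        mats = [normalize(m, scales) for m in mats]
    D = pairwise_distances(mats, mats, method.window_w)
    return D, scales


def welch_one_sided(within: np.ndarray, between: np.ndarray) -> float:
    """p-value of the one-sided Welch t-test for mean(within) < mean(between)."""
    res = stats.ttest_ind(
        np.asarray(within, dtype=float),
        np.asarray(between, dtype=float),
        equal_var=False,
        alternative="less",
    )
    return float(res.pvalue)


def _within_between(
    D: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    within = [D[i, j] for i in idx_a for j in idx_a if i != j]
    within += [D[i, j] for i in idx_b for j in idx_b if i != j]
    between = [D[i, j] for i in idx_a for j in idx_b]
    between += [D[i, j] for i in idx_b for j in idx_a]
    return np.asarray(within), np.asarray(between)


def discernability_pmax(
    pres: Sequence[PreprocessedTrial],
    method: MethodConfig,
    D: np.ndarray | None = None,
) -> float:
    """Max p over all cross-quality movement-type pairs for one task's
    lab trials.  ``D`` may be passed to reuse a precomputed matrix."""
    if D is None:
        D, _ = lab_distance_matrix(pres, method)
    groups = _group_by_type(pres)
    qual = {mt: pres[idx[0]].quality for mt, idx in groups.items()}
    p_values = []
    for mt_a, mt_b in itertools.combinations(sorted(groups), 2):
        if qual[mt_a] == qual[mt_b]:
            continue
        ia, ib = groups[mt_a], groups[mt_b]
        if len(ia) < 2 or len(ib) < 2:
            raise ValueError(
                f"types {mt_a!r}/{mt_b!r} need >=2 trials each for the t-test"
            )
        within, between = _within_between(D, ia, ib)
        p_values.append(welch_one_sided(within, between))
    if not p_values:
        raise ValueError("no cross-quality movement-type pair: task cannot be assessed")
    return float(max(p_values))


def loto_accuracy(
    pres: Sequence[PreprocessedTrial],
    method: MethodConfig,
    D: np.ndarray | None = None,
) -> float:
    """Leave-one-trial-out 1-NN accuracy at the quality level.

    Each lab trial is classified against all remaining lab trials by
    minimum projected distance; distance ties go to the reference trial
    earliest in session order."""
    if len(pres) < 3:
        raise ValueError("need >=3 lab trials for leave-one-trial-out")
    if D is None:
        D, _ = lab_distance_matrix(pres, method)
    qualities = [p.quality for p in pres]
    if len(set(qualities)) < 2:
        raise ValueError("need >=2 quality classes")
    n = len(pres)
    hits = 0
    for i in range(n):
        others = [j for j in range(n) if j != i]
        dists = D[i, others]
        # np.argmin returns the first minimum: earliest-in-session tie-break
        j = others[int(np.argmin(dists))]
        if qualities[j] == qualities[i]:
            hits += 1
    return hits / n


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _evaluate_method(tasks: Mapping, method: MethodConfig) -> MethodRecord:
    """p_max = max over tasks; LOTO pooled over tasks (each task's trials
    are only compared among themselves — references never cross tasks)."""
    p_all = []
    hits = 0
    total = 0
    try:
        for task_id in sorted(tasks):
            pres = tasks[task_id]
            D, _ = lab_distance_matrix(pres, method)
            p_all.append(discernability_pmax(pres, method, D))
            acc = loto_accuracy(pres, method, D)
            hits += round(acc * len(pres))
            total += len(pres)
    except InfeasibleWindowError:
        return MethodRecord(method=method, p_max=None, feasible=False, loto_accuracy=None)
    return MethodRecord(
        method=method,
        p_max=float(max(p_all)),
        feasible=True,
        loto_accuracy=hits / total,
    )


def _preference_key(m: MethodConfig) -> tuple:
    subset_order = [
        combo
        for r in range(1, len(CHANNEL_GROUPS) + 1)
        for combo in itertools.combinations(CHANNEL_GROUPS, r)
    ]
    return (
        m.channels != PREFERRED_CHANNELS or not m.normalize,  # preferred combo first
        -m.window_w,  # longer warping window
        subset_order.index(m.channels),  # canonical channel-set order
        not m.normalize,
    )


def group_lab_by_task(
    session: Session,
    filter_params: FilterParams | None = None,
    gravity_estimator: str = "kalman",
) -> dict:
    """Preprocess a lab session once, grouped by task."""
    tasks: dict = {}
    for tr in session.trials:
        tasks.setdefault(tr.task_id, []).append(
            preprocess_trial(tr, filter_params, gravity_estimator)
        )
    return tasks


def select_method(
    lab: Session | Mapping,
    grid: Sequence[MethodConfig],
    alpha: float = 0.05,
    filter_params: FilterParams | None = None,
    gravity_estimator: str = "kalman",
) -> SelectionResult:
    """Pick the participant's analysis method from the grid.

    ``lab`` is a lab Session or an already-preprocessed mapping
    task_id -> list of PreprocessedTrial.
    """
    if not grid:
        raise ConfigurationError("empty method grid")
    if isinstance(lab, Session):
        tasks = group_lab_by_task(lab, filter_params, gravity_estimator)
    else:
        tasks = dict(lab)

    records = [_evaluate_method(tasks, m) for m in grid]
    trace: list = []

    feasible = [r for r in records if r.feasible]
    if not feasible:
        raise InfeasibleWindowError("every method in the grid is infeasible")
    trace.append(f"feasible: {len(feasible)}/{len(records)} methods")

    passing = [r for r in feasible if r.p_max < alpha]
    if passing:
        candidates = passing
        trace.append(f"p_max < {alpha}: {len(candidates)} candidates")
    else:
        best_p = min(r.p_max for r in feasible)
        candidates = [r for r in feasible if r.p_max == best_p]
        trace.append(
            f"no method passed alpha={alpha}; argmin p_max={best_p:.4g} "
            f"leaves {len(candidates)} candidates"
        )

    if len(candidates) > 1:
        best_acc = max(r.loto_accuracy for r in candidates)
        candidates = [r for r in candidates if r.loto_accuracy == best_acc]
        trace.append(
            f"max LOTO accuracy {best_acc:.4f}: {len(candidates)} candidates"
        )

    if len(candidates) > 1:
        candidates = sorted(candidates, key=lambda r: _preference_key(r.method))
        trace.append(
            "tie-break preference (lin_acc+grav+gyro normalized, longer window, "
            f"canonical order) -> {candidates[0].method.label()}"
        )
    selected = candidates[0].method
    trace.append(f"selected: {selected.label()}")
    logger.info("method selection: %s", "; ".join(trace))
    return SelectionResult(records=records, selected=selected, selection_trace=trace)
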