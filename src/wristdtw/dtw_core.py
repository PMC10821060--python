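"""Windowed multivariate dynamic time warping with projected distance.

The aligner is the classic O(T_test * T_ref) dynamic program over the
local cost c(i, j) = ||test_i - ref_j||_2 (dependent multivariate DTW),
restricted to a Sakoe-Chiba band |i - j| <= w.  Two quantities come out:

* ``raw_cost`` — the accumulated cost along the optimal path, the
  standard DTW distance;
* ``projected_distance`` — the reference is first *projected* onto the
  test trial's time base (reference samples matched to each test index
  are averaged), then the mean per-test-sample Euclidean distance is
  taken.  Normalizing by the test length makes distances comparable
  across trials of different durations, which is what the downstream
  nearest-neighbor classifier needs.  This projected distance is the
  distance used everywhere downstream.

Tie-breaking in the DP backtrack is diagonal-first, then test-advancing,
so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .preprocessing import ChannelMatrix


class InfeasibleWindowError(ValueError):
    """The band is narrower than the length difference: no valid path."""


@dataclass(frozen=True)
class WarpPath:
    """Monotone alignment between test (i) and reference (j) indices."""

    i: np.ndarray  # 0-based test indices
    j: np.ndarray  # 0-based reference indices

    def __len__(self) -> int:
        return int(self.i.shape[0])

    def pairs(self):
        return list(zip(self.i.tolist(), self.j.tolist()))

    def validate(self, n_test: int, n_ref: int, window: int) -> None:
        i, j = self.i, self.j
        assert i[0] == 0 and j[0] == 0
        assert i[-1] == n_test - 1 and j[-1] == n_ref - 1
        di, dj = np.diff(i), np.diff(j)
        steps = set(zip(di.tolist(), dj.tolist()))
        assert steps <= {(1, 0), (0, 1), (1, 1)}
        assert np.all(np.abs(i - j) <= window)


@dataclass(frozen=True)
class DtwResult:
    path: WarpPath
    raw_cost: float
    projected_distance: float


@njit(cache=True)
def _dtw_dp(test, ref, w):  # pragma: no cover - numba
    n = test.shape[0]
    m = ref.shape[0]
    c = test.shape[1]
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo = i - w
        if jlo < 1:
            jlo = 1
        jhi = i + w
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            d = 0.0
            for k in range(c):
                diff = test[i - 1, k] - ref[j - 1, k]
                d += diff * diff
            d = np.sqrt(d)
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = d + best
    return D


@njit(cache=True)
def _dtw_backtrack(D, n, m):  # pragma: no cover - numba
    # diagonal-first, then test-advancing (i-1, j), then (i, j-1)
    max_len = n + m
    pi = np.empty(max_len, dtype=np.int64)
    pj = np.empty(max_len, dtype=np.int64)
    i, j = n, m
    k = max_len
    while i > 0 or j > 0:
        k -= 1
        pi[k] = i - 1
        pj[k] = j - 1
        if i == 1 and j == 1:
            i, j = 0, 0
        elif i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag = D[i - 1, j - 1]
            up = D[i - 1, j]
            left = D[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
    return pi[k:], pj[k:]


@njit(cache=True)
def _project_mean_distance(test, ref, pi, pj):  # pragma: no cover - numba
    n = test.shape[0]
    c = test.shape[1]
    proj = np.zeros((n, c))
    count = np.zeros(n)
    for p in range(pi.shape[0]):
        i = pi[p]
        for k in range(c):
            proj[i, k] += ref[pj[p], k]
        count[i] += 1.0
    total = 0.0
    for i in range(n):
        d = 0.0
        for k in range(c):
            diff = test[i, k] - proj[i, k] / count[i]
            d += diff * diff
        total += np.sqrt(d)
    return total / n


def _as_array(x) -> np.ndarray:
    if isinstance(x, ChannelMatrix):
        return np.ascontiguousarray(x.values)
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return np.ascontiguousarray(a)


def dtw_align(test, ref, window_w: int) -> DtwResult:
    """Band-constrained DTW between two channel matrices.

    ``test`` anchors the time base of the projected distance.  Raises
    InfeasibleWindowError when the band cannot reach the opposite corner
    (w < |T_test - T_ref|) — callers must widen the window, a silent huge
    distance would poison the nearest-neighbor step.
    """
    ta, ra = _as_array(test), _as_array(ref)
    if ta.shape[1] != ra.shape[1]:
        raise ValueError("test and ref must share the channel set")
    n, m = ta.shape[0], ra.shape[0]
    if window_w < abs(n - m):
        raise InfeasibleWindowError(
            f"window {window_w} < length difference {abs(n - m)}"
        )
    D = _dtw_dp(ta, ra, int(window_w))
    raw = float(D[n, m])
    pi, pj = _dtw_backtrack(D, n, m)
    proj = float(_project_mean_distance(ta, ra, pi, pj))
    return DtwResult(path=WarpPath(i=pi, j=pj), raw_cost=raw, projected_distance=proj)


def projected_distance(test, ref, path: WarpPath) -> float:
    """Mean per-test-sample Euclidean distance after projecting the
    reference onto the test time base along ``path``."""
    ta, ra = _as_array(test), _as_array(ref)
    return float(
        _project_mean_distance(
            ta, ra, np.ascontiguousarray(path.i), np.ascontiguousarray(path.j)
        )
    )


def dtw_projected(test, ref, window_w: int) -> float:
    """Convenience: align and return only the projected distance."""
    return dtw_align(test, ref, window_w).projected_distance


def pairwise_distances(trials_a, trials_b, window_w: int) -> np.ndarray:
    """Projected-distance matrix D[a, b] with trials_a[a] as test.

    Not symmetric in general: the projection is test-anchored.  A
    self-comparison (same object in both lists) lands on an exact zero.
    Infeasible pairs raise with the offending indices attached.
    """
    out = np.empty((len(trials_a), len(trials_b)))
    for a, ta in enumerate(trials_a):
        for b, rb in enumerate(trials_b):
            if ta is rb:
                out[a, b] = 0.0
                continue
            try:
                out[a, b] = dtw_align(ta, rb, window_w).projected_distance
            except InfeasibleWindowError as exc:
                raise InfeasibleWindowError(
                    f"pair (test={a}, ref={b}): {exc}"
                ) from exc
    return out
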