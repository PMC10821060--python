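"""Discernability t-test, LOTO accuracy, and the selection rule."""

import itertools

import numpy as np
import pytest

from wristdtw.data_io import ImuTrial
from wristdtw.method_selection import (
    DEFAULT_WINDOWS,
    MethodConfig,
    default_grid,
    discernability_pmax,
    lab_distance_matrix,
    loto_accuracy,
    select_method,
    welch_one_sided,
)
from wristdtw.preprocessing import PreprocessedTrial, preprocess_trial

from oracles import welch_p_one_sided


# ---------------------------------------------------------------------------
# Welch t-test against the closed-form oracle
# ---------------------------------------------------------------------------

def test_welch_hand_sample():
    p = welch_one_sided([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert p == pytest.approx(welch_p_one_sided([1, 2, 3], [4, 5, 6]), abs=1e-10)
    assert p < 0.05  # clearly separated means


@pytest.mark.parametrize("seed", range(20))
def test_welch_matches_closed_form_on_random_samples(seed):
    r = np.random.default_rng(seed)
    x = r.normal(0, 1, r.integers(3, 15)).tolist()
    y = r.normal(r.uniform(-2, 2), r.uniform(0.5, 3), r.integers(3, 15)).tolist()
    assert welch_one_sided(x, y) == pytest.approx(welch_p_one_sided(x, y), abs=1e-10)


def test_welch_separated_clusters_tiny_p(rng):
    within = rng.normal(0.0, 1e-6, 8)
    between = 5.0 + rng.normal(0.0, 1e-6, 8)
    assert welch_one_sided(within, between) < 1e-6


def test_welch_null_is_roughly_uniform(rng):
    hits = sum(
        welch_one_sided(rng.normal(size=10), rng.normal(size=10)) < 0.05
        for _ in range(200)
    )
    assert hits <= 20  # ~5% expected; generous binomial allowance


# ---------------------------------------------------------------------------
# discernability and LOTO on constructed trial sets
# ---------------------------------------------------------------------------

def _fake_pre(values, movement_type, quality, trial_id, rng):
    """PreprocessedTrial carrying a prescribed gyro stream; linear
    acceleration is uninformative noise, gravity is constant."""
    n = len(values)
    arr = np.zeros((n, 3))
    arr[:, 0] = values
    tr = ImuTrial(
        "P", 1, "lab", movement_type, quality, np.arange(n) / 100.0,
        np.tile([0.0, 0.0, 9.80665], (n, 1)), arr, np.zeros((n, 3)),
        trial_id=trial_id or movement_type,
    )
    return PreprocessedTrial(
        trial=tr,
        streams={"lin_acc": rng.normal(0, 0.05, (n, 3)), "grav": tr.acc,
                 "gyro": arr, "mag": tr.mag},
        fs=100.0,
    )


def _two_class_set(rng, sep=5.0, n_per=4, n_samp=30):
    pres = []
    for i in range(n_per):
        base = rng.normal(0, 0.05, n_samp)
        pres.append(_fake_pre(base, "correct", "correct", f"c{i}", rng))
    for i in range(n_per):
        base = sep + rng.normal(0, 0.05, n_samp)
        pres.append(_fake_pre(base, "compens", "incorrect", f"i{i}", rng))
    return pres


def test_pmax_separated_classes_is_tiny(rng):
    pres = _two_class_set(rng)
    method = MethodConfig(("gyro",), False, 50)
    assert discernability_pmax(pres, method) < 1e-6


def test_pmax_invariant_to_trial_order(rng):
    pres = _two_class_set(rng)
    method = MethodConfig(("gyro",), False, 50)
    p1 = discernability_pmax(pres, method)
    shuffled = [pres[i] for i in rng.permutation(len(pres))]
    assert discernability_pmax(shuffled, method) == pytest.approx(p1, rel=1e-12)


def test_pmax_requires_cross_quality_pair(rng):
    pres = [_fake_pre(rng.normal(size=30), f"t{k}", "correct", f"t{k}{i}", rng)
            for k in range(2) for i in range(2)]
    with pytest.raises(ValueError):
        discernability_pmax(pres, MethodConfig(("gyro",), False, 50))


def test_loto_well_separated_classes_is_perfect(rng):
    pres = _two_class_set(rng)
    assert loto_accuracy(pres, MethodConfig(("gyro",), False, 50)) == 1.0


def test_loto_single_outlier_costs_one_trial(rng):
    pres = _two_class_set(rng, n_per=4)
    # place one "correct" trial in the incorrect cluster: its own 1-NN is wrong,
    # everyone else is unaffected
    outlier = _fake_pre(5.5 + rng.normal(0, 0.05, 30), "correct", "correct", "out", rng)
    pres.append(outlier)
    n = len(pres)
    acc = loto_accuracy(pres, MethodConfig(("gyro",), False, 50))
    assert acc == pytest.approx((n - 1) / n)


def test_loto_all_identical_resolved_by_tie_break():
    vals = np.zeros(30)
    r = np.random.default_rng(0)
    pres = [
        _fake_pre(vals, "correct", "correct", "c0", r),
        _fake_pre(vals, "correct", "correct", "c1", r),
        _fake_pre(vals, "compens", "incorrect", "i0", r),
        _fake_pre(vals, "compens", "incorrect", "i1", r),
    ]
    # every distance is 0; earliest-reference tie-break means each trial is
    # labeled by the first *other* trial in session order
    acc = loto_accuracy(pres, MethodConfig(("gyro",), False, 50))
    # c0<-c1 hit, c1<-c0 hit, i0<-c0 miss, i1<-c0 miss
    assert acc == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# selection rule
# ---------------------------------------------------------------------------

def test_single_method_grid_selects_it(rng):
    pres = _two_class_set(rng)
    grid = [MethodConfig(("gyro",), False, 50)]
    res = select_method({1: pres}, grid)
    assert res.selected == grid[0]
    assert res.records[0].feasible


def test_alpha_rule_ignores_loto_when_only_one_passes(rng):
    pres = _two_class_set(rng)
    good = MethodConfig(("gyro",), True, 50)
    # linear acceleration is pure noise here: p_max stays large
    bad = MethodConfig(("lin_acc",), True, 50)
    res = select_method({1: pres}, [bad, good])
    assert res.selected == good
    recs = {r.method: r for r in res.records}
    assert recs[good].p_max < 0.05 < recs[bad].p_max


def test_adding_strictly_worse_method_never_changes_selection(rng):
    pres = _two_class_set(rng)
    good = MethodConfig(("gyro",), True, 100)
    worse = MethodConfig(("lin_acc",), False, 50)
    res_without = select_method({1: pres}, [good])
    res_with = select_method({1: pres}, [good, worse])
    assert res_without.selected == res_with.selected == good


def test_tie_break_prefers_canonical_combo_and_longer_window(rng):
    """On an all-tie grid (every method passes alpha with perfect LOTO and
    identical windows behave identically), the preference rule picks
    lin_acc+grav+gyro, normalized, with the longest window."""
    pres = _two_class_set(rng, sep=8.0)
    grid = default_grid(windows=(100, 200))
    res = select_method({1: pres}, grid)
    preferred = [r for r in res.records
                 if r.feasible and r.p_max < 0.05 and r.loto_accuracy == 1.0]
    assert len(preferred) > 1  # the tie-break was actually exercised
    assert any("tie-break" in step for step in res.selection_trace)
    assert res.selected.channels == ("lin_acc", "grav", "gyro")
    assert res.selected.normalize
    assert res.selected.window_w == 200


def test_selection_is_deterministic(rng):
    pres = _two_class_set(rng)
    grid = default_grid(windows=(50, 100))
    r1 = select_method({1: pres}, grid)
    r2 = select_method({1: pres}, grid)
    assert r1.selected == r2.selected
    assert r1.selection_trace == r2.selection_trace


def test_infeasible_windows_are_skipped(rng):
    pres = _two_class_set(rng, n_samp=30)
    pres.append(_fake_pre(rng.normal(0, 0.05, 120), "correct", "correct", "long", rng))
    narrow = MethodConfig(("gyro",), False, 10)  # cannot bridge 30 vs 120
    wide = MethodConfig(("gyro",), False, 100)
    res = select_method({1: pres}, [narrow, wide])
    recs = {r.method: r for r in res.records}
    assert not recs[narrow].feasible
    assert res.selected == wide


def test_default_grid_composition():
    grid = default_grid()
    assert len(grid) == 7 * 2 * len(DEFAULT_WINDOWS)
    assert all("mag" not in m.channels for m in grid)
    grid_mag = default_grid(include_mag=True)
    assert any("mag" in m.channels for m in grid_mag)
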