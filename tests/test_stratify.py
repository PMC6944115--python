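"""Cutoff-search stratification against brute-force oracles.

The scans are checked against independent from-definition enumerations on
small random cohorts, plus the structural invariants: ordering of marker
values across the split, rank (monotone-transform) invariance, and the
printed quadrant worked example.
"""

import math

import numpy as np
import pytest

from gliostrat.stratify import (
    ScanConstraints,
    dual_cutoff_fisher_scan,
    logrank_cutoff_scan,
    quadrant_table,
    survival_time_cutoff_scan,
)
from gliostrat.survival import SurvivalRecord, fisher_exact_two_sided


def make_records(times, events):
    return [SurvivalRecord(f"s{i}", float(t), int(e)) for i, (t, e) in enumerate(zip(times, events))]


def make_marker(values):
    return {f"s{i}": float(v) for i, v in enumerate(values)}


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, straight from the rule definitions)


def brute_dual_scan(marker, times, events, min_frac=0.1):
    """Enumerate every admissible split; survival cutoff = max hi time."""
    n = len(times)
    order = sorted(range(n), key=lambda i: (marker[i], i))
    min_size = max(2, math.ceil(min_frac * n))
    best = None
    for k in range(min_size, n - min_size + 1):
        vals = [marker[i] for i in order]
        if vals[k - 1] >= vals[k]:
            continue
        hi_idx = set(order[k:])
        scut = max(times[i] for i in hi_idx)
        a = b = c = d = 0
        for i in range(n):
            if events[i] == 0 and times[i] < scut:
                continue
            long_ = times[i] > scut
            if i in hi_idx:
                b += long_
                a += not long_
            else:
                d += long_
                c += not long_
        p = fisher_exact_two_sided(((a, b), (c, d)))
        hi_m = sorted(marker[i] for i in hi_idx)
        lo_m = sorted(marker[i] for i in range(n) if i not in hi_idx)
        med = abs(np.median(hi_m) - np.median(lo_m))
        imb = abs(len(hi_idx) - (n - len(hi_idx)))
        key = (p, -med, imb)
        if best is None or key < best[0]:
            best = (key, hi_idx, scut, p)
    return best


def brute_survival_time_scan(groups_hi, times, events):
    best = None
    for scut in sorted(set(times)):
        a = b = c = d = 0
        for i in range(len(times)):
            if events[i] == 0 and times[i] < scut:
                continue
            long_ = times[i] > scut
            if groups_hi[i]:
                b += long_
                a += not long_
            else:
                d += long_
                c += not long_
        p = fisher_exact_two_sided(((a, b), (c, d)))
        if best is None or p < best[1] * (1 - 1e-9):
            best = (scut, p)
    return best


def random_cohort(rng, n):
    marker = rng.normal(100, 30, n)
    times = rng.exponential(2.0, n) + 0.01
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[0] = 1
    return marker, times, events


# ---------------------------------------------------------------------------
# dual Fisher scan


def test_dual_scan_matches_brute_force_on_random_cohorts(rng):
    for _ in range(100):
        n = int(rng.integers(8, 31))
        marker, times, events = random_cohort(rng, n)
        res = dual_cutoff_fisher_scan(make_marker(marker), make_records(times, events))
        key, hi_idx, scut, p = brute_dual_scan(marker, times, events)
        got_hi = {int(s[1:]) for s, l in res.labels.items() if l == "hi"}
        assert res.p_fisher == pytest.approx(p, rel=1e-9)
        # set equality is only well-defined when the minimum is unique;
        # near-exact P ties fall to the (tolerance-based) tie-break chain
        others = [t["p_fisher"] for t in res.trace if t["p_fisher"] > p * (1 + 1e-6)]
        if len(others) == len(res.trace) - 1:
            assert got_hi == hi_idx
            assert res.survival_cutoff == pytest.approx(scut)


def test_dual_scan_ordering_invariant(rng):
    marker, times, events = random_cohort(rng, 24)
    res = dual_cutoff_fisher_scan(make_marker(marker), make_records(times, events))
    hi_vals = [marker[int(s[1:])] for s, l in res.labels.items() if l == "hi"]
    lo_vals = [marker[int(s[1:])] for s, l in res.labels.items() if l == "lo"]
    assert max(lo_vals) < min(hi_vals)
    assert res.n_hi + res.n_lo == 24
    # excluded censored samples are all censored below the survival cutoff
    for s in res.excluded_censored:
        i = int(s[1:])
        assert events[i] == 0 and times[i] < res.survival_cutoff


def test_dual_scan_monotone_transform_invariance(rng):
    marker, times, events = random_cohort(rng, 20)
    recs = make_records(times, events)
    res1 = dual_cutoff_fisher_scan(make_marker(marker), recs)
    res2 = dual_cutoff_fisher_scan(make_marker(np.exp(marker / 50.0)), recs)
    assert res1.labels == res2.labels
    assert res1.p_fisher == pytest.approx(res2.p_fisher)


def test_dual_scan_small_toy_attains_minimum_over_admissible_splits(rng):
    # n=8 cohort: every admissible split hand-enumerable through the trace
    marker = [10, 20, 30, 40, 50, 60, 70, 80]
    times = [0.5, 3.0, 0.7, 2.5, 4.0, 0.6, 0.9, 0.8]
    events = [1] * 8
    res = dual_cutoff_fisher_scan(make_marker(marker), make_records(times, events))
    trace_ps = [t["p_fisher"] for t in res.trace]
    assert len(trace_ps) == 5  # min group size 2 -> 5 admissible splits
    assert res.p_fisher == pytest.approx(min(trace_ps))


def test_dual_scan_constant_marker_errors():
    times = [1, 2, 3, 4, 5, 6]
    with pytest.raises(ValueError, match="constant"):
        dual_cutoff_fisher_scan(make_marker([5] * 6), make_records(times, [1] * 6))


def test_dual_scan_too_few_samples_errors():
    with pytest.raises(ValueError, match="at least 6"):
        dual_cutoff_fisher_scan(make_marker([1, 2, 3]), make_records([1, 2, 3], [1, 1, 1]))


def test_dual_scan_joint_never_worse_than_two_step(rng):
    marker, times, events = random_cohort(rng, 20)
    recs = make_records(times, events)
    two_step = dual_cutoff_fisher_scan(make_marker(marker), recs)
    joint = dual_cutoff_fisher_scan(make_marker(marker), recs, joint=True)
    assert joint.p_fisher <= two_step.p_fisher + 1e-12


# ---------------------------------------------------------------------------
# log-rank scan


def test_logrank_scan_single_admissible_split_returned():
    # marker admits exactly one split under min_group_fraction=0.4 (n=10)
    marker = [1] * 5 + [2] * 5
    times = [0.2, 0.3, 0.4, 0.5, 0.6, 2, 3, 4, 5, 6]
    res = logrank_cutoff_scan(
        make_marker(marker),
        make_records(times, [1] * 10),
        ScanConstraints(min_group_fraction=0.4),
    )
    assert res.n_hi == 5 and res.n_lo == 5
    assert len(res.trace) == 1


def test_logrank_scan_recovers_planted_hazard_split(rng):
    # hazard ratio 4 at a known marker threshold, 50/50
    hits = 0
    for _ in range(100):
        n = 60
        marker = np.concatenate([rng.uniform(0, 45, 30), rng.uniform(55, 100, 30)])
        times = np.concatenate([rng.exponential(4.0, 30), rng.exponential(1.0, 30)]) + 0.01
        res = logrank_cutoff_scan(make_marker(marker), make_records(times, np.ones(n)))
        if abs(res.n_lo - 30) <= 2:
            hits += 1
    assert hits >= 90  # within 2 rank positions of the planted threshold


def test_logrank_scan_requires_events():
    marker = list(range(10))
    with pytest.raises(ValueError, match="event"):
        logrank_cutoff_scan(make_marker(marker), make_records([1] * 10, [0] * 10))


def test_logrank_scan_reports_composite_score_trace(rng):
    marker, times, events = random_cohort(rng, 20)
    res = logrank_cutoff_scan(make_marker(marker), make_records(times, events))
    assert all("score" in t and "p_logrank" in t for t in res.trace)
    best_score = min(t["score"] for t in res.trace)
    chosen = [t for t in res.trace if t["n_hi"] == res.n_hi][0]
    assert chosen["score"] == pytest.approx(best_score)


# ---------------------------------------------------------------------------
# survival-time cutoff scan


def test_survival_time_scan_perfect_separation():
    groups = {f"s{i}": ("hi" if i < 5 else "lo") for i in range(10)}
    times = [0.5, 0.7, 0.9, 1.1, 1.3, 3.0, 3.5, 4.0, 4.5, 5.0]
    cutoff, table, p = survival_time_cutoff_scan(groups, make_records(times, [1] * 10))
    assert 1.3 <= cutoff < 3.0
    assert table == ((5, 0), (0, 5))
    assert p == pytest.approx(fisher_exact_two_sided(((5, 0), (0, 5))))


def test_survival_time_scan_matches_brute_force(rng):
    for _ in range(100):
        n = 12
        times = np.round(rng.exponential(2.0, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        hi = rng.integers(0, 2, n).astype(bool)
        if hi.all() or (~hi).all():
            hi[0] = ~hi[0]
        groups = {f"s{i}": ("hi" if h else "lo") for i, h in enumerate(hi)}
        cutoff, _, p = survival_time_cutoff_scan(groups, make_records(times, events))
        bcut, bp = brute_survival_time_scan(hi, times, events)
        assert p == pytest.approx(bp, rel=1e-9)
        assert cutoff == pytest.approx(bcut)


def test_survival_time_scan_identical_groups_p_one():
    groups = {f"s{i}": ("hi" if i % 2 else "lo") for i in range(8)}
    times = [1, 1, 2, 2, 3, 3, 4, 4]
    _, _, p = survival_time_cutoff_scan(groups, make_records(times, [1] * 8))
    assert p == pytest.approx(1.0)


def test_survival_time_scan_single_time_errors():
    groups = {"s0": "hi", "s1": "lo"}
    with pytest.raises(ValueError, match="distinct"):
        survival_time_cutoff_scan(groups, make_records([2, 2], [1, 1]))


# ---------------------------------------------------------------------------
# quadrant tables


def test_quadrant_table_printed_worked_example():
    """Cross-tabulating the study's two marker groups reproduces the printed
    quadrant counts and conditional percentages."""
    labels_a = {}
    labels_b = {}
    idx = 0
    for count, (la, lb) in [((16), ("hi", "hi")), ((10), ("hi", "lo")),
                            ((13), ("lo", "hi")), ((34), ("lo", "lo"))]:
        for _ in range(count):
            labels_a[f"s{idx}"] = la
            labels_b[f"s{idx}"] = lb
            idx += 1
    table, p = quadrant_table(labels_a, labels_b)
    assert table == ((16, 10), (13, 34))
    # conditional percentages of the shared-high quadrant
    assert 100 * table[0][0] / (table[0][0] + table[0][1]) == pytest.approx(61.5, abs=0.05)
    assert 100 * table[0][0] / (table[0][0] + table[1][0]) == pytest.approx(55.2, abs=0.05)
    assert 0 < p < 1


def test_quadrant_table_degenerate_all_hi():
    labels = {f"s{i}": "hi" for i in range(6)}
    table, p = quadrant_table(labels, labels)
    assert table == ((6, 0), (0, 0))
    assert p == 1.0


def test_quadrant_table_equals_direct_fisher(rng):
    la = {f"s{i}": ("hi" if v else "lo") for i, v in enumerate(rng.integers(0, 2, 20))}
    lb = {f"s{i}": ("hi" if v else "lo") for i, v in enumerate(rng.integers(0, 2, 20))}
    table, p = quadrant_table(la, lb)
    assert p == pytest.approx(fisher_exact_two_sided(table))


def test_quadrant_table_no_shared_samples_errors():
    with pytest.raises(ValueError, match="shared|labeled"):
        quadrant_table({"a": "hi"}, {"b": "lo"})
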