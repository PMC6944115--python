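"""Survival-driven cutoff-search stratification.

The study's group-definition machinery: given a continuous marker (an IHC
H-score, an mRNA level or a signature-enrichment score) and overall-survival
data, find the marker cutoff that best separates a poor-prognosis "hi" group
from the remaining "lo" samples.  Three scans are provided:

``dual_cutoff_fisher_scan``
    For every admissible marker cutoff, set the survival-time cutoff to the
    longest survival observed in the hi group, cross-tabulate hi/lo against
    short/long survivor (censored observations below the survival cutoff are
    excluded from the table), and keep the split minimizing the two-sided
    Fisher exact P.  This encodes the defining observation that the
    highest-marker tumors contain no long survivors.

``logrank_cutoff_scan``
    Evaluate the log-rank P of every admissible split and select by a
    composite rank score that also rewards balanced group sizes and large
    median-survival differences.

``survival_time_cutoff_scan``
    With groups fixed, scan candidate survival-time cutoffs for the one
    minimizing the Fisher P of the hi/lo x short/long table (used for
    external cohorts where the hi-group maximum is not meaningful).

Minimum-P selection is anti-conservative: the scanned minimal P is biased
below its nominal distribution and is reported un-corrected, flagged as
selection-biased in the result metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from gliostrat.survival import (
    SurvivalRecord,
    _km_arrays,
    _logrank_arrays,
    fisher_exact_two_sided,
)

__all__ = [
    "ScanConstraints",
    "StratificationResult",
    "dual_cutoff_fisher_scan",
    "logrank_cutoff_scan",
    "survival_time_cutoff_scan",
    "quadrant_table",
]

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ScanConstraints:
    """Constraints and selection weights for the cutoff scans.

    min_group_fraction
        Smallest admissible fraction of samples per group (each group also
        needs at least 2 members).
    balance_weight, median_diff_weight
        Weights of the group-balance and median-difference rank terms in the
        composite criterion of ``logrank_cutoff_scan``.
    """

    min_group_fraction: float = 0.1
    balance_weight: float = 1.0
    median_diff_weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_group_fraction <= 0.5:
            raise ValueError("min_group_fraction must be in (0, 0.5]")
        if self.balance_weight < 0 or self.median_diff_weight < 0:
            raise ValueError("weights must be >= 0")


@dataclass
class StratificationResult:
    """A chosen split with its contingency evidence and full scan trace."""

    marker: str
    expression_cutoff: float
    survival_cutoff: Optional[float]
    labels: dict[str, str]
    table: Optional[tuple[tuple[int, int], tuple[int, int]]]
    p_fisher: Optional[float]
    p_logrank: Optional[float]
    n_hi: int
    n_lo: int
    excluded_censored: list[str]
    trace: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "expression_cutoff": self.expression_cutoff,
            "survival_cutoff": self.survival_cutoff,
            "labels": self.labels,
            "table": self.table,
            "p_fisher": self.p_fisher,
            "p_logrank": self.p_logrank,
            "n_hi": self.n_hi,
            "n_lo": self.n_lo,
            "excluded_censored": self.excluded_censored,
            "trace": self.trace,
            "metadata": self.metadata,
        }


def _aligned(
    marker_values: Mapping[str, float], survival: Sequence[SurvivalRecord]
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Samples with both marker and survival, sorted by (marker, id)."""
    by_id = {r.sample_id: r for r in survival}
    ids = [s for s in marker_values if s in by_id]
    if not ids:
        raise ValueError("no samples with both marker and survival data")
    ids.sort(key=lambda s: (marker_values[s], s))
    m = np.array([marker_values[s] for s in ids], dtype=float)
    t = np.array([by_id[s].time for s in ids], dtype=float)
    e = np.array([by_id[s].event for s in ids], dtype=int)
    return ids, m, t, e


def _admissible_lo_sizes(m: np.ndarray, min_group_fraction: float) -> list[int]:
    """Sizes k of the lo group (the k smallest marker values) that form a valid split."""
    n = len(m)
    min_size = max(2, math.ceil(min_group_fraction * n))
    sizes = [
        k for k in range(min_size, n - min_size + 1) if m[k - 1] < m[k]
    ]
    return sizes


def _quadrant_counts(
    t: np.ndarray, e: np.ndarray, hi: np.ndarray, scut: float
) -> tuple[tuple[tuple[int, int], tuple[int, int]], np.ndarray]:
    """hi/lo x short/long table, excluding censored observations below scut."""
    excluded = (e == 0) & (t < scut)
    keep = ~excluded
    long_ = t > scut
    a = int(np.sum(hi & keep & ~long_))
    b = int(np.sum(hi & keep & long_))
    c = int(np.sum(~hi & keep & ~long_))
    d = int(np.sum(~hi & keep & long_))
    return ((a, b), (c, d)), excluded


def _better(cand: tuple, best: Optional[tuple]) -> bool:
    """Selection order: smaller P, then larger |median diff|, then smaller imbalance."""
    if best is None:
        return True
    p_c, med_c, imb_c = cand
    p_b, med_b, imb_b = best
    if not np.isclose(p_c, p_b, rtol=_TIE_RTOL, atol=0.0):
        return p_c < p_b
    if not np.isclose(med_c, med_b, rtol=_TIE_RTOL, atol=0.0):
        return med_c > med_b
    return imb_c < imb_b


def dual_cutoff_fisher_scan(
    marker_values: Mapping[str, float],
    survival: Sequence[SurvivalRecord],
    constraints: ScanConstraints = ScanConstraints(),
    marker: str = "marker",
    joint: bool = False,
) -> StratificationResult:
    """Minimum-Fisher-P search for paired expression and survival cutoffs.

    Candidate expression cutoffs are midpoints between consecutive distinct
    sorted marker values.  By default (``joint=False``) the survival cutoff of
    each candidate is the longest survival time observed in its hi group; with
    ``joint=True`` the survival cutoff is additionally scanned over observed
    times and the minimizing pair is returned.
    """
    ids, m, t, e = _aligned(marker_values, survival)
    n = len(ids)
    if n < 6:
        raise ValueError(f"need at least 6 samples with marker and survival, got {n}")
    if np.all(m == m[0]):
        raise ValueError("marker is constant: no valid split exists")
    sizes = _admissible_lo_sizes(m, constraints.min_group_fraction)
    if not sizes:
        raise ValueError("no admissible split satisfies the group-size constraint")

    trace: list[dict] = []
    best_key: Optional[tuple] = None
    best: Optional[dict] = None
    for k in sizes:
        hi = np.zeros(n, dtype=bool)
        hi[k:] = True
        if joint:
            scut_candidates = np.unique(t)
        else:
            scut_candidates = [float(np.max(t[hi]))]
        for scut in scut_candidates:
            table, excluded = _quadrant_counts(t, e, hi, float(scut))
            p = fisher_exact_two_sided(table)
            med_diff = abs(float(np.median(m[hi]) - np.median(m[~hi])))
            imbalance = abs(int(np.sum(hi)) - int(np.sum(~hi)))
            cutoff = 0.5 * (m[k - 1] + m[k])
            entry = {
                "expression_cutoff": float(cutoff),
                "survival_cutoff": float(scut),
                "n_hi": int(np.sum(hi)),
                "n_lo": int(np.sum(~hi)),
                "table": table,
                "p_fisher": p,
            }
            trace.append(entry)
            key = (p, med_diff, imbalance)
            if _better(key, best_key):
                best_key = key
                best = {**entry, "hi": hi.copy(), "excluded": excluded.copy()}
    assert best is not None
    labels = {s: ("hi" if h else "lo") for s, h in zip(ids, best["hi"])}
    excluded_ids = [s for s, x in zip(ids, best["excluded"]) if x]
    return StratificationResult(
        marker=marker,
        expression_cutoff=best["expression_cutoff"],
        survival_cutoff=best["survival_cutoff"],
        labels=labels,
        table=best["table"],
        p_fisher=best["p_fisher"],
        p_logrank=None,
        n_hi=best["n_hi"],
        n_lo=best["n_lo"],
        excluded_censored=excluded_ids,
        trace=trace,
        metadata={
            "method": "dual_cutoff_fisher_scan",
            "joint": joint,
            "min_group_fraction": constraints.min_group_fraction,
            "selection_biased_p": True,
        },
    )


def _median_or_rmean_diff(
    t: np.ndarray, e: np.ndarray, hi: np.ndarray
) -> float:
    """|KM median difference|, falling back to restricted means when undefined."""
    tmax = float(np.max(t))
    meds = []
    rmeans = []
    for mask in (hi, ~hi):
        uniq, probs, _, _ = _km_arrays(t[mask], e[mask])
        if uniq.size == 0:
            meds.append(math.inf)
            rmeans.append(tmax)
            continue
        below = np.nonzero(probs <= 0.5)[0]
        meds.append(float(uniq[below[0]]) if below.size else math.inf)
        # restricted mean: area under the step function up to tmax
        times = np.concatenate([[0.0], np.clip(uniq, 0, tmax), [tmax]])
        heights = np.concatenate([[1.0], probs])
        rmeans.append(float(np.sum(np.diff(times) * heights)))
    if all(math.isfinite(v) for v in meds):
        return abs(meds[0] - meds[1])
    return abs(rmeans[0] - rmeans[1])


def logrank_cutoff_scan(
    marker_values: Mapping[str, float],
    survival: Sequence[SurvivalRecord],
    constraints: ScanConstraints = ScanConstraints(),
    marker: str = "marker",
) -> StratificationResult:
    """Constrained log-rank scan over all admissible ordered splits.

    Every candidate is scored by
    ``rank(P) + balance_weight * rank(imbalance) - median_diff_weight * rank(|median diff|)``
    (ranks across candidates, lower score wins; ties broken by smaller P).
    The weights concretize the verbal rule of picking low P while
    equilibrating group sizes and maximizing the survival separation.
    """
    ids, m, t, e = _aligned(marker_values, survival)
    n = len(ids)
    if n < 6:
        raise ValueError(f"need at least 6 samples with marker and survival, got {n}")
    if np.all(m == m[0]):
        raise ValueError("marker is constant: no valid split exists")
    if not np.any(e == 1):
        raise ValueError("log-rank scan requires at least one event")
    sizes = _admissible_lo_sizes(m, constraints.min_group_fraction)
    if not sizes:
        raise ValueError("no admissible split satisfies the group-size constraint")

    cand = []
    for k in sizes:
        hi = np.zeros(n, dtype=bool)
        hi[k:] = True
        stat, p = _logrank_arrays(t[hi], e[hi], t[~hi], e[~hi])
        imbalance = abs(int(np.sum(hi)) - int(np.sum(~hi))) / n
        med_diff = _median_or_rmean_diff(t, e, hi)
        cand.append(
            {
                "k": k,
                "expression_cutoff": float(0.5 * (m[k - 1] + m[k])),
                "n_hi": n - k,
                "n_lo": k,
                "statistic": stat,
                "p_logrank": p,
                "imbalance": imbalance,
                "median_diff": med_diff,
            }
        )
    p_rank = rankdata([c["p_logrank"] for c in cand])
    imb_rank = rankdata([c["imbalance"] for c in cand])
    med_rank = rankdata([c["median_diff"] for c in cand])
    scores = (
        p_rank
        + constraints.balance_weight * imb_rank
        - constraints.median_diff_weight * med_rank
    )
    for c, s in zip(cand, scores):
        c["score"] = float(s)
    best = min(cand, key=lambda c: (c["score"], c["p_logrank"], c["k"]))
    hi = np.zeros(n, dtype=bool)
    hi[best["k"] :] = True
    labels = {s: ("hi" if h else "lo") for s, h in zip(ids, hi)}
    return StratificationResult(
        marker=marker,
        expression_cutoff=best["expression_cutoff"],
        survival_cutoff=None,
        labels=labels,
        table=None,
        p_fisher=None,
        p_logrank=best["p_logrank"],
        n_hi=best["n_hi"],
        n_lo=best["n_lo"],
        excluded_censored=[],
        trace=cand,
        metadata={
            "method": "logrank_cutoff_scan",
            "min_group_fraction": constraints.min_group_fraction,
            "balance_weight": constraints.balance_weight,
            "median_diff_weight": constraints.median_diff_weight,
            "selection_biased_p": True,
        },
    )


def survival_time_cutoff_scan(
    groups: Mapping[str, str],
    survival: Sequence[SurvivalRecord],
) -> tuple[float, tuple[tuple[int, int], tuple[int, int]], float]:
    """Scan survival-time cutoffs for fixed hi/lo groups, minimizing Fisher P.

    Candidates are the observed survival times; censored observations below a
    candidate cutoff are excluded from its table.  Returns the minimizing
    (cutoff, table, P); ties resolve to the smallest cutoff.
    """
    recs = [r for r in survival if r.sample_id in groups]
    if not recs:
        raise ValueError("no samples shared between groups and survival data")
    hi = np.array([groups[r.sample_id] == "hi" for r in recs])
    if hi.all() or (~hi).all():
        raise ValueError("both hi and lo groups must be non-empty")
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=int)
    cutoffs = np.unique(t)
    if cutoffs.size < 2:
        raise ValueError("need at least two distinct survival times to scan")
    best = None
    for scut in cutoffs:
        table, _ = _quadrant_counts(t, e, hi, float(scut))
        p = fisher_exact_two_sided(table)
        if best is None or p < best[2] * (1.0 - _TIE_RTOL):
            best = (float(scut), table, p)
    assert best is not None
    return best


def quadrant_table(
    labels_a: Mapping[str, str], labels_b: Mapping[str, str]
) -> tuple[tuple[tuple[int, int], tuple[int, int]], float]:
    """Cross-tabulate two hi/lo labelings over their shared samples.

    Rows are factor A (hi, lo), columns factor B (hi, lo); returns the 2x2
    table and its two-sided Fisher exact P.
    """
    shared = [s for s in labels_a if s in labels_b]
    if not shared:
        raise ValueError("no samples labeled under both factors")
    a = sum(1 for s in shared if labels_a[s] == "hi" and labels_b[s] == "hi")
    b = sum(1 for s in shared if labels_a[s] == "hi" and labels_b[s] == "lo")
    c = sum(1 for s in shared if labels_a[s] == "lo" and labels_b[s] == "hi")
    d = sum(1 for s in shared if labels_a[s] == "lo" and labels_b[s] == "lo")
    table = ((a, b), (c, d))
    return table, fisher_exact_two_sided(table)
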