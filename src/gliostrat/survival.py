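"""Survival and contingency statistics for cutoff-search stratification.

Kaplan–Meier product-limit estimation, the two-group log-rank test and the
restricted-mean fallback are implemented directly on numpy arrays: the
stratification scans evaluate them for every candidate split and the null
calibrations run thousands of replicates, so per-call overhead matters.
The implementations are cross-checked against lifelines in the test suite.
Fisher's exact test, the Pearson chi-square and the nonparametric group
comparisons delegate to scipy.

Conventions
-----------
* event status 1 = dead, 0 = censored; times are positive and in years;
* censored observations tied with event times are taken to occur *after*
  the events (they remain in the risk set of those events);
* the two-sided Fisher P sums hypergeometric point probabilities not larger
  than the observed one (the "minimum-likelihood" definition, scipy's and
  R's default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "records_from_frame",
    "km_estimate",
    "median_survival",
    "restricted_mean",
    "logrank_test",
    "fisher_exact_two_sided",
    "pearson_chi2",
    "group_compare",
    "read_clinical",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's overall-survival observation."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event status must be 0 or 1, got {self.event}")


@dataclass
class KMCurve:
    """Right-continuous Kaplan–Meier step function.

    ``survival_probs[i]`` is S(t) for ``event_times[i] <= t < event_times[i+1]``;
    S(t) = 1 before the first event time.
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray = field(default=None)  # events at each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Build records from a clinical table with sample_id, time, event columns."""
    return [
        SurvivalRecord(str(r.sample_id), float(r.time), int(r.event))
        for r in df.itertuples()
    ]


def _as_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([r.time for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=int)
    return t, e


def _km_arrays(times: np.ndarray, events: np.ndarray):
    """Distinct event times, survival probabilities and risk-set sizes."""
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    n = len(t)
    # risk set at time t = number of observations with time >= t
    ev_t = t[e == 1]
    if ev_t.size == 0:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int)
    uniq, d = np.unique(ev_t, return_counts=True)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    probs = np.cumprod(1.0 - d / at_risk)
    return uniq, probs, at_risk, d


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    t, e = _as_arrays(records)
    uniq, probs, at_risk, d = _km_arrays(t, e)
    return KMCurve(uniq, probs, at_risk, d)


def median_survival(curve: KMCurve) -> float:
    """Smallest event time with S(t) <= 0.5; ``inf`` when never reached."""
    below = np.nonzero(curve.survival_probs <= 0.5)[0]
    return float(curve.event_times[below[0]]) if below.size else inf


def restricted_mean(curve: KMCurve, tmax: float) -> float:
    """Area under the KM curve up to ``tmax`` (restricted mean survival time)."""
    times = np.concatenate([[0.0], curve.event_times, [tmax]])
    probs = np.concatenate([[1.0], curve.survival_probs, [0.0]])  # last prob unused
    times = np.clip(times, 0.0, tmax)
    # step function: S is constant on [times[i], times[i+1])
    widths = np.diff(times)
    return float(np.sum(widths * np.concatenate([[1.0], curve.survival_probs])[: len(widths)]))


def _logrank_arrays(
    t1: np.ndarray, e1: np.ndarray, t2: np.ndarray, e2: np.ndarray
) -> tuple[float, float]:
    ev1 = np.sort(t1[e1 == 1])
    ev2 = np.sort(t2[e2 == 1])
    if ev1.size + ev2.size == 0:
        raise ValueError("log-rank test undefined without any event")
    ev_times = np.unique(np.concatenate([ev1, ev2]))
    t1s = np.sort(t1)
    t2s = np.sort(t2)
    n1 = len(t1s) - np.searchsorted(t1s, ev_times, side="left")
    n2 = len(t2s) - np.searchsorted(t2s, ev_times, side="left")
    nt = n1 + n2
    # events at each distinct event time, per group, by counting in sorted arrays
    d1 = np.searchsorted(ev1, ev_times, side="right") - np.searchsorted(ev1, ev_times, side="left")
    d2 = np.searchsorted(ev2, ev_times, side="right") - np.searchsorted(ev2, ev_times, side="left")
    dt = d1 + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = dt * n1 / nt
        var = np.where(
            nt > 1,
            dt * (n1 / nt) * (1.0 - n1 / nt) * (nt - dt) / np.maximum(nt - 1, 1),
            0.0,
        )
    v = float(np.sum(var))
    o_minus_e = float(np.sum(d1 - expected))
    if v <= 0.0:
        # all events concentrated where one group has the full risk set
        return 0.0, 1.0
    stat = o_minus_e**2 / v
    return stat, float(stats.chi2.sf(stat, df=1))


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank chi-square on 1 df and its upper-tail P.

    Tied event times use the hypergeometric variance; raises if neither
    group contains an event.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = _as_arrays(group_a)
    tb, eb = _as_arrays(group_b)
    return _logrank_arrays(ta, ea, tb, eb)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact P for a 2x2 table ``[[a, b], [c, d]]``.

    Degenerate margins (an empty row or column) return 1.0.
    """
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for an r x c table."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)


def _dunn_pairwise(values_by_group: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Dunn's z-tests on pooled ranks with tie correction, unadjusted two-sided P."""
    names = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in names])
    sizes = {g: len(values_by_group[g]) for g in names}
    ranks = stats.rankdata(pooled)
    big_n = len(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        mean_rank[g] = float(np.mean(ranks[start : start + sizes[g]]))
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (big_n - 1))
    out: dict[tuple[str, str], float] = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            se = sqrt(
                (big_n * (big_n + 1) / 12.0 - tie_term)
                * (1.0 / sizes[gi] + 1.0 / sizes[gj])
            )
            z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
            out[(gi, gj)] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def group_compare(
    values_by_group: Mapping[str, Sequence[float]], method: str = "auto"
) -> dict:
    """Nonparametric comparison of marker values across groups.

    Two groups: two-sided Mann–Whitney U.  More than two: Kruskal–Wallis
    omnibus followed by Dunn's pairwise z-tests (unadjusted).  Returns a dict
    with ``omnibus_p`` and per-comparison ``pairwise`` P-values.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 1 for v in groups.values()):
        raise ValueError("every group needs at least one observation")
    names = list(groups)
    if method not in ("auto", "mann_whitney", "kruskal_wallis_dunn"):
        raise ValueError(f"unknown method {method!r}")
    if len(groups) == 2 and method in ("auto", "mann_whitney"):
        u, p = stats.mannwhitneyu(groups[names[0]], groups[names[1]], alternative="two-sided")
        return {"omnibus_p": float(p), "pairwise": {(names[0], names[1]): float(p)}, "U": float(u)}
    if method == "mann_whitney":
        raise ValueError("mann_whitney requires exactly two groups")
    stat, p = stats.kruskal(*groups.values())
    return {"omnibus_p": float(p), "pairwise": _dunn_pairwise(groups), "H": float(stat)}


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical CSV with sample_id, time, event and free covariates."""
    df = pd.read_csv(path)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive survival times for samples {bad}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event status must be 0 (censored) or 1 (dead)")
    df["sample_id"] = df["sample_id"].astype(str)
    return df
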