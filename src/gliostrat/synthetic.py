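"""Synthetic glioma cohorts with known ground truth.

The generator emulates the statistical structure every other module assumes,
so the whole pipeline is testable without any download:

* a "hi" subgroup (default 30% of samples) whose survival is exponential but
  truncated below a fixed horizon — no hi-group patient survives past it —
  while the remaining samples follow an untruncated exponential that does
  produce long survivors;
* a continuous IHC-style marker (H-score on [0, 300]) separating the two
  groups, together with pixel-bin counts that regenerate each H-score
  through the scoring formula;
* log2-scale expression with a planted upregulated gene program in the hi
  group;
* an immune admixture: per-sample tumor purity (anti-correlated with the
  marker) and a nontumor compartment mixed from cell-type reference
  profiles over dedicated marker genes.

Everything planted is recorded in a truth dictionary so recovery can be
scored without re-deriving ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from gliostrat.ihc import PixelBinCounts, hscore

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "generate_reference_matrix", "write_cohort"]

_MARKERS_PER_TYPE = 10
_PIXEL_TOTAL = 20000
_MAX_REJECTION_ROUNDS = 10000


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort; defaults mirror the study conditions.

    n_samples=30 matches the transcriptome cohort; hi_fraction=0.3 the
    marker-high subgroup; survival_cutoff_true=1.8 years the horizon beyond
    which no hi-group patient survives.  hazard_lo=0.7/year leaves ~26% of
    the lo group alive past the horizon (the cohort's long-survivor rate);
    hazard_hi=2.0/year with truncation keeps hi-group survival short.
    """

    n_samples: int = 30
    hi_fraction: float = 0.3
    survival_cutoff_true: float = 1.8
    hazard_hi: float = 2.0
    hazard_lo: float = 0.7
    censor_rate: float = 0.15
    n_genes: int = 1000
    n_signature_genes: int = 30
    signature_effect_log2: float = 1.5
    noise_sd: float = 0.5
    n_cell_types: int = 5
    purity_range: tuple[float, float] = (0.4, 0.95)
    marker_infiltrate_corr: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if round(self.hi_fraction * self.n_samples) < 2:
            raise ValueError("infeasible config: hi group would have < 2 samples")
        if self.n_samples - round(self.hi_fraction * self.n_samples) < 2:
            raise ValueError("infeasible config: lo group would have < 2 samples")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_signature_genes + _MARKERS_PER_TYPE * self.n_cell_types > self.n_genes:
            raise ValueError("n_genes too small for the planted program and cell-type markers")
        if not -1.0 <= self.marker_infiltrate_corr <= 1.0:
            raise ValueError("marker_infiltrate_corr must be in [-1, 1]")
        if not 0.0 <= self.purity_range[0] < self.purity_range[1] <= 1.0:
            raise ValueError("purity_range must satisfy 0 <= lo < hi <= 1")


@dataclass
class SyntheticCohort:
    """In-memory bundle of one generated cohort plus its ground truth."""

    clinical: pd.DataFrame
    marker_scores: pd.DataFrame
    pixel_counts: pd.DataFrame
    expression: pd.DataFrame
    reference: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _truncated_exponential(rng, scale: float, upper: float, size: int) -> np.ndarray:
    """Rejection-sampled Exp(scale) conditioned on being below ``upper``."""
    out = rng.exponential(scale, size)
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = out >= upper
        if not bad.any():
            return out
        out[bad] = rng.exponential(scale, int(bad.sum()))
    raise RuntimeError(
        f"rejection sampling failed to stay below {upper} after "
        f"{_MAX_REJECTION_ROUNDS} rounds (scale={scale})"
    )


def _administrative_censoring(rng, t_true: np.ndarray, rate: float):
    """Uniform(0, Cmax) follow-up limits with Cmax solved for the target rate."""
    if rate <= 0:
        return t_true.copy(), np.ones(len(t_true), dtype=int)

    def expected_rate(cmax: float) -> float:
        return float(np.mean(np.minimum(t_true / cmax, 1.0)))

    lo, hi = 1e-3, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_rate(mid) > rate:
            lo = mid
        else:
            hi = mid
    cmax = 0.5 * (lo + hi)
    c = rng.uniform(0.0, cmax, len(t_true))
    event = (t_true <= c).astype(int)
    t_obs = np.minimum(t_true, c)
    # survival times must stay positive
    t_obs = np.maximum(t_obs, 1e-3)
    return t_obs, event


def _pixel_bins_for_hscore(rng, h: float) -> PixelBinCounts:
    """Pixel-bin counts whose H-score reproduces ``h`` to < 0.1 units."""
    m = h / 100.0  # target mean intensity in [0, 3]
    for _ in range(1000):
        x = rng.dirichlet(np.ones(4))[1:]  # raw proportions for bins 1..3
        s = x[0] + 2 * x[1] + 3 * x[2]
        if s <= 0:
            continue
        f = m / s
        if f * x.sum() <= 1.0:
            p = f * x
            break
    else:  # deterministic fallback: all weight in the strong bin
        p = np.array([0.0, 0.0, m / 3.0])
    n1 = int(round(p[0] * _PIXEL_TOTAL))
    n2 = int(round(p[1] * _PIXEL_TOTAL))
    n3 = int(round(p[2] * _PIXEL_TOTAL))
    n0 = _PIXEL_TOTAL - n1 - n2 - n3
    if n0 < 0:  # rounding overshoot by at most a couple of pixels
        n1 = max(0, n1 + n0)
        n0 = _PIXEL_TOTAL - n1 - n2 - n3
    return PixelBinCounts(n0, n1, n2, n3)


def generate_reference_matrix(config: CohortConfig) -> pd.DataFrame:
    """Cell-type reference signature matrix (genes x cell types, linear scale).

    Each type owns a disjoint block of marker genes (elevated 16-fold over a
    shared baseline), yielding well-conditioned, non-negative profiles.  The
    condition number is recorded in ``DataFrame.attrs``.  Deterministic
    under the config seed.
    """
    if config.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(config.seed + 1_000_003)
    genes = _gene_ids(config.n_genes)
    start = config.n_signature_genes
    ref_genes = genes[start : start + _MARKERS_PER_TYPE * config.n_cell_types]
    base = np.power(2.0, rng.uniform(5.0, 8.0, len(ref_genes)))
    profiles = np.tile(base[:, None], (1, config.n_cell_types))
    for c in range(config.n_cell_types):
        block = slice(c * _MARKERS_PER_TYPE, (c + 1) * _MARKERS_PER_TYPE)
        profiles[block, c] *= 16.0
    ref = pd.DataFrame(
        profiles, index=ref_genes, columns=[f"celltype_{c}" for c in range(config.n_cell_types)]
    )
    ref.attrs["condition_number"] = float(np.linalg.cond(profiles))
    return ref


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort: clinical, marker, pixel, expression and truth.

    Deterministic given the config seed.  The hi group contains zero
    survivors past ``survival_cutoff_true`` by construction (hard invariant).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_hi = int(round(config.hi_fraction * n))
    ids = [f"S{i:03d}" for i in range(n)]
    hi_mask = np.zeros(n, dtype=bool)
    hi_mask[rng.choice(n, size=n_hi, replace=False)] = True

    # --- survival -----------------------------------------------------------
    t_true = np.empty(n)
    t_true[hi_mask] = _truncated_exponential(
        rng, 1.0 / config.hazard_hi, config.survival_cutoff_true, n_hi
    )
    t_true[~hi_mask] = rng.exponential(1.0 / config.hazard_lo, n - n_hi)
    t_true = np.maximum(t_true, 1e-3)
    t_obs, event = _administrative_censoring(rng, t_true, config.censor_rate)
    # censoring must not break the defining truncation of the hi group
    assert (t_obs[hi_mask] <= config.survival_cutoff_true).all()
    clinical = pd.DataFrame({"sample_id": ids, "time": t_obs, "event": event})

    # --- marker + pixel bins ------------------------------------------------
    marker = np.empty(n)
    marker[hi_mask] = rng.uniform(180.0, 295.0, n_hi)
    marker[~hi_mask] = rng.uniform(10.0, 150.0, n - n_hi)
    pixel_rows = []
    score_rows = []
    for i, s in enumerate(ids):
        counts = _pixel_bins_for_hscore(rng, marker[i])
        pixel_rows.append(
            {"sample_id": s, "marker": "marker", "n0": counts.n0, "n1": counts.n1,
             "n2": counts.n2, "n3": counts.n3}
        )
        score_rows.append(
            {"sample_id": s, "marker": "marker", "kind": "hscore", "value": hscore(counts)}
        )
    pixel_counts = pd.DataFrame(pixel_rows)
    marker_scores = pd.DataFrame(score_rows)

    # --- purity and nontumor composition ------------------------------------
    z_marker = (marker - marker.mean()) / marker.std()
    rho = config.marker_infiltrate_corr
    w = rho * z_marker + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    p_lo, p_hi = config.purity_range
    purity = p_lo + (p_hi - p_lo) * (1.0 - norm.cdf(w))
    rel_fracs = rng.dirichlet(np.ones(config.n_cell_types), size=n)

    # --- expression ----------------------------------------------------------
    genes = _gene_ids(config.n_genes)
    mu = rng.uniform(4.0, 10.0, config.n_genes)
    log2_tumor = mu[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n))
    expr_lin = np.power(2.0, log2_tumor)
    reference = generate_reference_matrix(config)
    ref_idx = [genes.index(g) for g in reference.index]
    nontumor = reference.to_numpy() @ rel_fracs.T  # ref genes x samples
    expr_lin[ref_idx, :] = (
        purity[None, :] * expr_lin[ref_idx, :] + (1.0 - purity)[None, :] * nontumor
    )
    expression = pd.DataFrame(np.log2(expr_lin), index=genes, columns=ids)
    program_genes = genes[: config.n_signature_genes]
    expression.loc[program_genes, hi_mask] += config.signature_effect_log2

    # --- truth ---------------------------------------------------------------
    truth = {
        "config": {**asdict(config), "purity_range": list(config.purity_range)},
        "sample_ids": ids,
        "hi_samples": [s for s, h in zip(ids, hi_mask) if h],
        "marker": {s: float(v) for s, v in zip(ids, marker)},
        "true_times": {s: float(v) for s, v in zip(ids, t_true)},
        "realized_censor_rate": float(np.mean(event == 0)),
        "program_genes": program_genes,
        "cell_type_markers": {
            c: list(reference.index[i * _MARKERS_PER_TYPE : (i + 1) * _MARKERS_PER_TYPE])
            for i, c in enumerate(reference.columns)
        },
        "purity": {s: float(v) for s, v in zip(ids, purity)},
        "relative_fractions": {
            s: {c: float(v) for c, v in zip(reference.columns, rel_fracs[i])}
            for i, s in enumerate(ids)
        },
    }
    return SyntheticCohort(clinical, marker_scores, pixel_counts, expression, reference, truth)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write the cohort as plain-text files; byte-deterministic given a seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": out / "clinical.csv",
        "marker": out / "marker.csv",
        "pixel_counts": out / "pixel_counts.csv",
        "expression": out / "expression.tsv",
        "reference": out / "reference.tsv",
        "truth": out / "truth.json",
    }
    cohort.clinical.to_csv(paths["clinical"], index=False)
    cohort.marker_scores.to_csv(paths["marker"], index=False)
    cohort.pixel_counts.to_csv(paths["pixel_counts"], index=False)
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    cohort.reference.to_csv(paths["reference"], sep="\t", index_label="gene_id")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return paths
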