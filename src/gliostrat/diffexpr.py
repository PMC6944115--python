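"""Expression filtering, moderated differential expression and signature search.

Expression matrices are pandas DataFrames with gene identifiers as the index
and sample identifiers as columns, on the log2 scale throughout.

The two-group differential expression test uses empirical-Bayes variance
moderation: per-gene residual variances are shrunk toward a common prior
estimated by moment matching of the log residual variances (digamma /
trigamma inversion), and the moderated t-statistic is referred to a
t-distribution with ``d0 + d`` degrees of freedom.  Setting ``prior_df=0``
recovers the ordinary two-sample t-test exactly.

``build_signature`` implements the iterative prognostic-signature search:
a second differential-expression round over a pre-selected gene universe, a
grid of (logFC, FDR) thresholds anchored at the study's printed values, and
selection of the candidate gene set whose sample-wise enrichment scores,
dichotomized at a fixed cutoff, best separate short from long survivors by
Fisher's exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from gliostrat.enrichment import sample_enrichment_scores
from gliostrat.survival import SurvivalRecord, fisher_exact_two_sided

__all__ = [
    "detection_filter",
    "collapse_genes",
    "reference_gene_filter",
    "moderated_de",
    "select_degs",
    "hypergeometric_ora",
    "SignatureResult",
    "build_signature",
]

DEFAULT_GRID: tuple[tuple[float, float], ...] = ((0.89, 0.015), (1.12, 0.022))


# ---------------------------------------------------------------------------
# filtering


def detection_filter(
    matrix: pd.DataFrame, detect_p: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Drop genes whose detection P-value is >= ``alpha`` in every sample.

    ``detect_p`` must be aligned with ``matrix`` (same genes and samples);
    a gene detected in even a single sample is retained.
    """
    if detect_p.shape != matrix.shape:
        raise ValueError(
            f"detection P matrix shape {detect_p.shape} does not match "
            f"expression shape {matrix.shape}"
        )
    detect_p = detect_p.loc[matrix.index, matrix.columns]
    undetected_everywhere = (detect_p.to_numpy() >= alpha).all(axis=1)
    return matrix.loc[~undetected_everywhere]


def collapse_genes(matrix: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe/transcript-cluster rows to one row per gene.

    Among rows mapping to the same gene, the row with the highest mean
    intensity is kept (max-intensity collapsing).
    """
    if not mapping:
        raise ValueError("empty row-to-gene mapping")
    missing = [r for r in matrix.index if r not in mapping]
    if missing:
        raise ValueError(f"mapping does not cover rows: {missing[:5]}")
    genes = matrix.index.map(lambda r: mapping[r])
    means = matrix.mean(axis=1).to_numpy()
    keep_rows = (
        pd.DataFrame({"gene": genes, "mean": means, "row": matrix.index})
        .sort_values(["gene", "mean", "row"])
        .groupby("gene", sort=True)
        .tail(1)["row"]
    )
    out = matrix.loc[keep_rows]
    out.index = [mapping[r] for r in out.index]
    out.index.name = matrix.index.name
    return out


def reference_gene_filter(matrix: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Keep genes with both median and sd above the reference gene's.

    The reference gene itself is always retained.  This focuses downstream
    analyses on transcripts at least as well expressed and as variable as the
    marker transcript.
    """
    if reference_gene not in matrix.index:
        raise ValueError(f"reference gene {reference_gene!r} not in matrix")
    med = matrix.median(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    keep = (med > med[reference_gene]) & (sd > sd[reference_gene])
    keep[reference_gene] = True
    return matrix.loc[keep]


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-F prior (prior df d0 and variance s0^2).

    Matches the mean and variance of log(s2) to the theoretical moments of a
    log scaled F-distribution; returns (d0, s0sq), with d0 = inf when the
    observed log-variances are no more dispersed than sampling alone implies.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return math.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0sq


def moderated_de(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Two-group differential expression with empirical-Bayes moderation.

    Parameters
    ----------
    matrix
        log2 expression, genes x samples.
    groups
        sample_id -> "hi" | "lo"; samples absent from the mapping are ignored.
    prior_df
        Override for the prior degrees of freedom d0.  ``None`` estimates d0
        and the prior variance from the data; ``0`` disables moderation
        (ordinary t-test); ``inf`` shrinks every gene fully to the prior.

    Returns
    -------
    DataFrame indexed by gene with columns logFC (hi minus lo mean, log2),
    t (moderated), p and fdr (Benjamini–Hochberg), sorted by p.
    """
    hi_samples = [s for s in matrix.columns if groups.get(s) == "hi"]
    lo_samples = [s for s in matrix.columns if groups.get(s) == "lo"]
    n1, n2 = len(hi_samples), len(lo_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (hi={n1}, lo={n2})")
    x1 = matrix[hi_samples].to_numpy(dtype=float)
    x2 = matrix[lo_samples].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    logfc = m1 - m2
    df_resid = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0sq = _fit_f_dist(s2, df_resid)
    elif prior_df == 0:
        d0, s0sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0sq = _fit_f_dist(s2, df_resid)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"logFC": logfc, "t": tstat, "p": p, "fdr": fdr}, index=matrix.index
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0sq
    out.attrs["residual_df"] = df_resid
    return out.sort_values("p")


def select_degs(
    de: pd.DataFrame,
    fdr_max: float,
    abs_lfc_min: float,
    direction: str = "both",
) -> list[str]:
    """Genes with fdr < ``fdr_max`` and |logFC| >= ``abs_lfc_min``.

    ``direction="up"`` additionally restricts to positive logFC.
    """
    if direction not in ("both", "up"):
        raise ValueError(f"unknown direction {direction!r}")
    mask = (de["fdr"] < fdr_max) & (de["logFC"].abs() >= abs_lfc_min)
    if direction == "up":
        mask &= de["logFC"] > 0
    return list(de.index[mask])


# ---------------------------------------------------------------------------
# over-representation analysis


def hypergeometric_ora(
    hits: Sequence[str],
    universe: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    p_cutoff: float = 0.001,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    Sets are intersected with the universe first; sets whose intersected size
    falls outside ``[min_size, max_size]`` are skipped.  Returns a DataFrame
    with set_size, overlap, p and the enrichment flag ``p < p_cutoff``.
    """
    uni = set(universe)
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ValueError("hit list must be a subset of the universe")
    big_n = len(uni)
    n_hits = len(hit_set)
    rows = []
    for name, genes in sets.items():
        inset = set(genes) & uni
        k_set = len(inset)
        if not min_size <= k_set <= max_size:
            continue
        overlap = len(inset & hit_set)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, k_set, n_hits))
        rows.append(
            {
                "set": name,
                "set_size": k_set,
                "overlap": overlap,
                "p": p,
                "enriched": p < p_cutoff,
            }
        )
    return pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["set_size", "overlap", "p", "enriched"]
    )


# ---------------------------------------------------------------------------
# signature construction


@dataclass
class SignatureResult:
    """A prognostic gene signature selected by survival separation."""

    genes: list[str]
    thresholds_used: tuple[float, float]  # (logfc_min, fdr_max)
    separation_p: float
    enrichment_cutoff: float
    table: tuple[tuple[int, int], tuple[int, int]]
    scores: pd.Series = None
    trace: list[dict] = field(default_factory=list)


def _separation_table(
    scores: pd.Series,
    survival: Sequence[SurvivalRecord],
    survival_cutoff: float,
    enrichment_cutoff: float,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Enriched/under-represented x short/long table, censored-below excluded."""
    a = b = c = d = 0
    for r in survival:
        if r.sample_id not in scores.index:
            continue
        if r.event == 0 and r.time < survival_cutoff:
            continue
        enriched = scores[r.sample_id] > enrichment_cutoff
        long_ = r.time > survival_cutoff
        if enriched and not long_:
            a += 1
        elif enriched and long_:
            b += 1
        elif not enriched and not long_:
            c += 1
        else:
            d += 1
    return ((a, b), (c, d))


def build_signature(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    survival: Sequence[SurvivalRecord],
    survival_cutoff: float,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    enrichment_cutoff: float = -0.05,
    score_matrix: Optional[pd.DataFrame] = None,
) -> SignatureResult:
    """Search a threshold grid for the upregulated gene set that best
    separates marker-high tumors from long survivors.

    A fresh moderated differential-expression round is run on ``matrix``
    (typically restricted to a previously selected gene universe, with all
    samples re-included).  For each grid point ``(logfc_min, fdr_max)`` the
    candidate signature is the set of upregulated genes passing it; every
    sample is scored by sample-wise enrichment of the candidate, scores are
    dichotomized at ``enrichment_cutoff``, and the two-sided Fisher P of the
    enriched x long-survivor table (censored below ``survival_cutoff``
    excluded) is computed.  The candidate with minimal P wins; ties go to the
    smaller signature.

    ``score_matrix`` lets the enrichment be computed on a wider matrix than
    the differential-expression universe (default: ``matrix`` itself).
    """
    de = moderated_de(matrix, groups)
    scoring = matrix if score_matrix is None else score_matrix
    best: Optional[SignatureResult] = None
    trace: list[dict] = []
    for logfc_min, fdr_max in grid:
        genes = select_degs(de, fdr_max=fdr_max, abs_lfc_min=logfc_min, direction="up")
        entry = {
            "logfc_min": logfc_min,
            "fdr_max": fdr_max,
            "n_genes": len(genes),
            "separation_p": None,
        }
        if len(genes) < 2:
            trace.append(entry)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = sample_enrichment_scores(scoring, {"signature": genes}).loc["signature"]
        table = _separation_table(scores, survival, survival_cutoff, enrichment_cutoff)
        p = fisher_exact_two_sided(table)
        entry["separation_p"] = p
        trace.append(entry)
        if (
            best is None
            or p < best.separation_p * (1 - 1e-12)
            or (np.isclose(p, best.separation_p, rtol=1e-9) and len(genes) < len(best.genes))
        ):
            best = SignatureResult(
                genes=genes,
                thresholds_used=(logfc_min, fdr_max),
                separation_p=p,
                enrichment_cutoff=enrichment_cutoff,
                table=table,
                scores=scores,
            )
    if best is None:
        raise ValueError("no grid point produced a candidate signature of >= 2 genes")
    best.trace = trace
    return best
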