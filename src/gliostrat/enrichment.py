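"""Sample-wise gene-set enrichment scoring, subtype calls and clustering.

The enrichment score is a rank-based, single-sample running-sum statistic in
the GSVA family.  For each gene, expression is rank-transformed *across*
samples and centered, so a gene's statistic says where the sample sits in
the cohort for that gene.  Within each sample, genes are ordered by that
statistic and a weighted Kolmogorov–Smirnov-like walk is taken down the
list: set genes push the sum up proportionally to the magnitude of their
statistic, non-set genes push it down by a constant.  The score is the
maximum positive deviation plus the maximum negative deviation of the walk
(the signed "mx.diff" combination), which is bounded in [-1, 1] because each
deviation is normalized by its theoretical maximum.

The rank transform replaces the kernel-density expression statistic of the
published method; only the ordering and the dichotomization of scores are
consumed downstream, and the rank statistic preserves both (and is exactly
invariant under monotone transformations of each gene's expression).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import rankdata

__all__ = [
    "sample_enrichment_scores",
    "signature_prefilter",
    "classify_subtype",
    "correlation_cluster",
]


def sample_enrichment_scores(
    matrix: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    tau: float = 1.0,
) -> pd.DataFrame:
    """Per-sample enrichment scores for each gene set, bounded in [-1, 1].

    Parameters
    ----------
    matrix
        log2 expression, genes x samples (>= 2 samples for a meaningful
        cross-sample rank).
    sets
        set name -> gene list.  Sets retaining fewer than 2 genes present in
        the matrix are dropped with a warning; if all sets drop, raises.
    tau
        Weight exponent on the gene-level statistic (1 = linear weights).

    Returns
    -------
    DataFrame of scores, set names x sample ids.
    """
    genes = matrix.index
    n_genes, n_samples = matrix.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes to score enrichment")
    expr = matrix.to_numpy(dtype=float)
    # rank each gene across samples, centered so the statistic is signed
    ranks = np.apply_along_axis(rankdata, 1, expr)
    z = ranks - (n_samples + 1) / 2.0

    gene_pos = {g: i for i, g in enumerate(genes)}
    kept: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        idx = np.array(sorted({gene_pos[g] for g in members if g in gene_pos}), dtype=int)
        if idx.size < 2:
            warnings.warn(f"gene set {name!r} retains < 2 matrix genes; dropped")
            continue
        if idx.size >= n_genes:
            warnings.warn(f"gene set {name!r} covers the whole matrix; dropped")
            continue
        kept[name] = idx
    if not kept:
        raise ValueError("no gene set retains >= 2 genes present in the matrix")

    in_set_masks = {}
    for name, idx in kept.items():
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        in_set_masks[name] = mask

    scores = np.zeros((len(kept), n_samples))
    # deterministic within-sample ordering: statistic descending, gene index as tie-break
    tie = np.broadcast_to(np.arange(n_genes)[:, None], z.shape)
    order = np.lexsort((tie, -z), axis=0)
    absz = np.abs(z) ** tau
    for j in range(n_samples):
        oj = order[:, j]
        w = absz[oj, j]
        for i, (name, idx) in enumerate(kept.items()):
            mask = in_set_masks[name][oj]
            wsum = w[mask].sum()
            m = idx.size
            if wsum <= 0:
                # all set genes sit exactly at the central rank; no signal
                scores[i, j] = 0.0
                continue
            steps = np.where(mask, w / wsum, -1.0 / (n_genes - m))
            walk = np.cumsum(steps)
            scores[i, j] = float(max(walk.max(), 0.0) + min(walk.min(), 0.0))
    return pd.DataFrame(scores, index=list(kept), columns=matrix.columns)


def signature_prefilter(
    matrix: pd.DataFrame, signature_genes: Sequence[str]
) -> pd.DataFrame:
    """Drop genes with both median and sd below every signature gene's.

    Mirrors the pre-scoring filter that removes transcripts less expressed
    and less variable than any member of the signature; signature genes are
    always retained.
    """
    sig = [g for g in signature_genes if g in matrix.index]
    if not sig:
        raise ValueError("no signature gene present in the matrix")
    med = matrix.median(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    min_med = med[sig].min()
    min_sd = sd[sig].min()
    keep = (med >= min_med) | (sd >= min_sd)
    keep[sig] = True
    return matrix.loc[keep]


def classify_subtype(
    scores: pd.DataFrame, tie_margin: float = 0.01
) -> dict[str, str]:
    """Assign each sample the label of its top-scoring set.

    When the top two scores differ by less than ``tie_margin`` the sample is
    labeled ``"nd"`` (not determined).
    """
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 subtype sets to classify")
    out: dict[str, str] = {}
    for sample in scores.columns:
        col = scores[sample].sort_values(ascending=False)
        if col.iloc[0] - col.iloc[1] < tie_margin:
            out[sample] = "nd"
        else:
            out[sample] = str(col.index[0])
    return out


def correlation_cluster(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage (UPGMA) clustering of samples under Pearson distance.

    Distance between samples is 1 - Pearson correlation over genes.
    Zero-variance genes are dropped with a warning (they carry no
    correlation information).  Returns the scipy linkage matrix and the
    sample order it indexes.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    var = matrix.var(axis=1, ddof=0)
    if (var == 0).any():
        warnings.warn(f"dropping {(var == 0).sum()} zero-variance genes")
        matrix = matrix.loc[var > 0]
    if matrix.shape[0] < 2:
        raise ValueError("fewer than 2 informative genes after dropping zero variance")
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    z = linkage(x, method="average", metric="correlation")
    return z, list(matrix.columns)
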