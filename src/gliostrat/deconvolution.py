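"""Immune/stromal scoring, tumor-purity estimation and cell-type deconvolution.

A bulk glioma sample is modeled as a mixture of malignant cells (fraction =
tumor purity) and a nontumor compartment of immune and stromal cells.  Three
steps are chained:

1. ``infiltrate_scores`` — sample-wise enrichment of immune and stromal gene
   sets; their sum is mapped onto a per-sample purity in [0, 1] by a strictly
   decreasing (by default affine, cohort-calibrated) map.
2. ``deconvolve`` — relative cell-type fractions by non-negative least
   squares of the linearized (2^x) expression on a reference signature
   matrix over the shared genes.  NNLS replaces the nu-SVR of the published
   deconvolution tool; recovery on known mixtures, not tool concordance, is
   the contract.
3. ``purity_correct`` — absolute fractions of the whole sample: relative
   fraction x (1 - purity), so absolute fractions plus purity account for
   the entire sample.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from gliostrat.enrichment import sample_enrichment_scores

__all__ = [
    "infiltrate_scores",
    "deconvolve",
    "purity_correct",
    "marker_fraction_correlation",
]


def _affine_purity_map(combined: pd.Series) -> pd.Series:
    """Strictly decreasing affine clamp of combined scores onto [0, 1].

    Calibrated on the cohort's observed score range: the lowest combined
    (immune + stromal) score maps to purity 1, the highest to 0.
    """
    lo, hi = float(combined.min()), float(combined.max())
    if hi - lo <= 1e-12:
        return pd.Series(0.5, index=combined.index)
    return ((hi - combined) / (hi - lo)).clip(0.0, 1.0)


def infiltrate_scores(
    matrix: pd.DataFrame,
    immune_set: Sequence[str],
    stromal_set: Sequence[str],
    purity_map: Optional[Callable[[pd.Series], pd.Series]] = None,
) -> pd.DataFrame:
    """Immune, stromal and combined infiltrate scores plus purity per sample.

    Both gene sets must share at least 2 genes with the matrix.  The purity
    map is pluggable (e.g. an externally trained calibration); the default is
    the cohort-range affine clamp.
    """
    sets = {"immune": list(immune_set), "stromal": list(stromal_set)}
    for name, genes in sets.items():
        if len(set(genes) & set(matrix.index)) < 2:
            raise ValueError(f"{name} set shares < 2 genes with the matrix")
    scores = sample_enrichment_scores(matrix, sets)
    combined = scores.loc["immune"] + scores.loc["stromal"]
    purity = (purity_map or _affine_purity_map)(combined)
    out = pd.DataFrame(
        {
            "immune_score": scores.loc["immune"],
            "stromal_score": scores.loc["stromal"],
            "combined_score": combined,
            "purity": purity,
        }
    )
    out.index.name = "sample_id"
    return out


def _collinear_columns(ref: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in exact collinearity (best effort, for errors)."""
    bad = []
    corr = np.corrcoef(ref.T)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isclose(abs(corr[i, j]), 1.0, atol=1e-10):
                bad.extend([names[i], names[j]])
    return sorted(set(bad)) or names


def deconvolve(
    matrix: pd.DataFrame,
    reference: pd.DataFrame,
    linearize: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Relative cell-type fractions per sample by non-negative least squares.

    Parameters
    ----------
    matrix
        Expression, genes x samples, log2 scale (``linearize=True`` applies
        2^x before fitting; pass ``False`` for data already linear).
    reference
        Signature matrix, genes x cell types, linear scale, non-negative.

    Returns
    -------
    (fractions, degenerate) — fractions is samples x cell types summing to 1
    per row; degenerate flags samples whose NNLS coefficients were all zero
    (those get uniform fractions).
    """
    if (reference.to_numpy() < 0).any():
        raise ValueError("reference signature matrix must be non-negative")
    if reference.shape[1] < 2:
        raise ValueError("reference needs at least 2 cell types")
    shared = [g for g in reference.index if g in matrix.index]
    k = reference.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} reference genes shared with the matrix; "
            f"need at least {k} (one per cell type)"
        )
    ref = reference.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(ref) < k:
        bad = _collinear_columns(ref, list(reference.columns))
        raise ValueError(f"reference matrix is rank-deficient; collinear columns: {bad}")
    y = matrix.loc[shared].to_numpy(dtype=float)
    if linearize:
        y = np.power(2.0, y)
    fracs = np.zeros((matrix.shape[1], k))
    degenerate = np.zeros(matrix.shape[1], dtype=bool)
    for j in range(matrix.shape[1]):
        coef, _ = nnls(ref, y[:, j])
        s = coef.sum()
        if s <= 0:
            fracs[j] = 1.0 / k
            degenerate[j] = True
        else:
            fracs[j] = coef / s
    return (
        pd.DataFrame(fracs, index=matrix.columns, columns=reference.columns),
        pd.Series(degenerate, index=matrix.columns, name="degenerate_fit"),
    )


def purity_correct(
    relative_fractions: pd.DataFrame, purity: pd.Series
) -> pd.DataFrame:
    """Absolute cell-type fractions of the whole sample.

    absolute = relative x (1 - purity); row sums equal the nontumor
    fraction, so fractions plus purity partition each sample.
    """
    purity = purity.loc[relative_fractions.index]
    if ((purity < 0) | (purity > 1)).any():
        bad = purity[(purity < 0) | (purity > 1)].index.tolist()
        raise ValueError(f"purity outside [0, 1] for samples {bad}")
    sums = relative_fractions.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("relative fractions must sum to 1 per sample")
    return relative_fractions.mul(1.0 - purity, axis=0)


def marker_fraction_correlation(
    fractions: Mapping[str, float] | pd.Series,
    marker: Mapping[str, float] | pd.Series,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation (r, two-sided p) between a cell-type fraction and a marker."""
    f = pd.Series(fractions, dtype=float)
    m = pd.Series(marker, dtype=float)
    shared = f.index.intersection(m.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired observations")
    fv, mv = f[shared].to_numpy(), m[shared].to_numpy()
    if np.all(fv == fv[0]) or np.all(mv == mv[0]):
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(fv, mv)
    elif method == "spearman":
        r, p = stats.spearmanr(fv, mv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
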