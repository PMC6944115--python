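# gliostrat

Survival-driven marker stratification, prognostic-signature construction and
immune-infiltrate deconvolution for glioma cohorts.

## The problem

High-grade gliomas are molecularly heterogeneous, and a recurring analysis
pattern in marker studies is: quantify a candidate protein marker by digital
immunohistochemistry (IHC), split the cohort into marker-high and marker-low
groups using the patients' survival as the guide, characterize the high
group's transcriptome, distill it into a reusable mRNA signature, and ask
whether the marker tracks immune infiltration.  Each of those steps hides a
bespoke computational procedure that is rarely shipped as tested code.  This
package implements the full chain as a library with a CLI, exercised end to
end on synthetic cohorts with known ground truth:

* **ihc** — digital IHC quantification.  Pixels are binned into intensity
  classes i = 0..3 with class percentages P_i; the H-score is
  `HSCORE = Σ_i i·P_i ∈ [0, 300]`, percent-strong is `P_3`, and
  mutation-specific stains are called mutant iff any staining is present.
* **survival** — Kaplan–Meier product-limit estimate
  `S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)`, the two-group log-rank test,
  median / restricted-mean survival, the two-sided Fisher exact test
  (minimum-likelihood definition) and Kruskal–Wallis/Dunn comparisons.
* **stratify** — the group-definition machinery.  The dual cutoff scan
  tries every admissible marker cutoff, pairs it with a survival-time
  cutoff equal to the longest survival in the candidate high group,
  cross-tabulates high/low against short/long survivor (censored
  observations below the survival cutoff are excluded) and keeps the split
  minimizing the Fisher P.  A constrained log-rank scan and a
  survival-time-only scan cover the other stratification variants, and all
  scans emit a full audit trace.  Scanned minimum P-values are reported
  uncorrected but flagged: they are selection-biased by construction.
* **diffexpr** — detection/collapse/reference-gene filters, two-group
  differential expression with empirical-Bayes variance moderation
  (posterior variance `(d₀s₀² + d s²)/(d₀ + d)`, moderated t on d₀+d df,
  Benjamini–Hochberg FDR), hypergeometric over-representation, and the
  grid-searched signature construction: candidate upregulated gene sets are
  scored per sample, dichotomized at an enrichment cutoff (default −0.05)
  and judged by how well they separate marker-high tumors from long
  survivors.
* **enrichment** — rank-based single-sample gene-set scoring (a weighted
  KS running sum over each sample's gene ranking; score = max positive +
  max negative deviation, bounded in [−1, 1]), subtype assignment by
  top-scoring set, and Pearson-distance/average-linkage clustering.
* **deconvolution** — immune/stromal scoring with a cohort-calibrated
  purity map, non-negative least squares of linearized (2^x) expression on
  a cell-type reference matrix, purity correction
  (absolute = relative × (1 − purity)), and marker–fraction correlations.
* **synthetic** — cohort generator with planted truth: a marker-high
  subgroup whose survival is truncated at 1.8 years (no long survivors), a
  planted upregulated gene program, pixel bins that regenerate the marker
  H-scores, and an immune admixture with known per-sample purity.

## Worked example

The `analysis/` scripts run the whole chain on a simulated cohort
(`python analysis/01_simulate_cohort.py` … `06_immune_deconvolution.py`).
Step 3, stratification, prints:

```
dual Fisher scan: cutoff 130.2, n_hi=10, n_lo=20, p=2.00e-04, planted-set overlap 9/9
log-rank scan: cutoff 109.2, n_hi=14, n_lo=16, p=1.77e-03, planted-set overlap 9/9
dual-scan survival cutoff: 0.84 y (longest hi-group survival); table ((10, 0), (5, 14)), 1 censored excluded
```

The dual scan recovered all 9 planted marker-high samples plus one extra —
the minimum-P rule prefers absorbing a short-surviving low sample because
that strictly sharpens the contingency table (see `docs/methods.md` on this
selection bias).  The table `((10, 0), (5, 14))` says: 10 high-marker
samples, none surviving past the cutoff; 19 low-marker samples of whom 14
are long survivors.  Step 4 then prints:

```
first DE round: 34 DEGs at FDR<0.015, |logFC|>=0.89 (prior df 100.2)
signature: 28 genes at thresholds (1.12, 0.022), separation p=0.0007
Jaccard with planted program: 0.87 (1 extra genes, 1 of them planted immune markers)
```

i.e. the grid-searched signature recovers the planted 30-gene program almost
exactly, and its single extra gene is one of the immune-admixture markers —
which are genuinely differentially expressed because infiltration is coupled
to the marker, mirroring how real marker signatures absorb immune genes.

A CLI mirrors the library (`gliostrat simulate|hscore|stratify|de|signature|
enrich|deconvolve|run`); `gliostrat run` executes the pipeline and writes a
manifest of SHA-256 hashes so a run is reproducible from its own output.

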