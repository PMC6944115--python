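# Methods

This note records the models, parameter choices and numerical conventions
behind each module, what the synthetic cohorts do and do not emulate, and
the known limitations.

## Digital IHC quantification

Input is a per-measurement vector of pixel counts in four staining
intensity classes (negative 0, weak 1, positive 2, strong 3), as produced
by slide-scanner pixel classifiers; image processing is out of scope.  The
H-score is Σ i·P_i over class percentages P_i (range 0–300), percent-strong
is the class-3 percentage, and mutation-specific stains are called mutant
iff any non-negative-class pixel exists.  Scores are kept at full floating
precision; rounding is for display only.  Aggregation across replicate
cores of one patient is left to the caller — the module scores one count
vector per call.

## Survival statistics

Kaplan–Meier, log-rank and restricted-mean survival are implemented
directly on numpy arrays because the cutoff scans and the null calibrations
below evaluate them tens of thousands of times; lifelines is the
independent oracle in the test suite, not the runtime dependency of the
scan loops.  Conventions: censored observations tied with an event time
remain in that event's risk set; tied events use the hypergeometric
variance; a comparison where one group has left every risk set before the
first event is reported as (statistic 0, P 1), matching lifelines.  The
two-sided Fisher exact P uses the minimum-likelihood definition (sum of
hypergeometric point probabilities ≤ the observed one), which is scipy's
and R's default and reproduces published values.  Median survival is the
smallest event time with S(t) ≤ 0.5, `inf` when the curve never crosses.

## Cutoff-search stratification

The dual scan implements a literal two-step rule: candidate expression
cutoffs are midpoints between consecutive distinct sorted marker values
(samples with tied values can never be split), each candidate's
survival-time cutoff is the longest survival observed in its high group,
and the high/low × short/long table excludes censored observations below
the survival cutoff.  Exclusion applies only to the table — never to KM or
log-rank computations.  Selection minimizes the two-sided Fisher P; exact
ties (relative tolerance 1e-9) fall to larger |median marker difference|,
then to smaller group imbalance.  A `joint=True` option additionally scans
the survival cutoff over observed times.

The log-rank scan evaluates every admissible split and selects by
`rank(P) + w_b·rank(imbalance) − w_m·rank(|Δmedian|)` with both weights
defaulting to 1 — our concretization of the verbal rule "lowest P while
equilibrating group sizes and maximizing the survival difference"; the
weights are configurable and echoed in the result metadata.  When a group's
KM median is undefined the median difference falls back to restricted means
over the observed time range.  `min_group_fraction` defaults to 0.1 (each
group also ≥ 2 samples) to block degenerate splits.

**Selection bias, and why exact cutpoint recovery is rare.**  Minimum-P
cutpoints are anti-conservative: under the null (marker independent of
survival, n = 50, all splits scanned) the median of the scanned minimal
log-rank P is ≈ 0.03 and the minimum is below 0.05 in ≈ 60% of replicates —
numbers the acceptance suite recomputes.  The same greediness shapes the
dual Fisher scan on cohorts with a planted marker-high group: absorbing a
short-surviving low-marker sample into the high group strictly lowers the
Fisher P (the table gains a consistent observation without losing a long
survivor), so the scan over-extends whenever the next sample down the
marker ranking is not a long survivor.  Exact recovery of a planted high
set therefore occurs at roughly the low group's long-survivor rate (~20–25%
under the default cohorts), even though the recovered set almost always
contains the planted one.  Scan outputs carry a `selection_biased_p` flag,
and no multiplicity correction is applied, deliberately mirroring the
source procedure.

## Differential expression and signature search

Per-gene two-group linear models with empirical-Bayes variance moderation:
residual variances s² (d = n₁+n₂−2 df) are shrunk toward a prior s₀² with
d₀ df estimated by moment matching of log s² (digamma/trigamma moments,
Newton inversion of the trigamma); the posterior variance is
(d₀s₀² + d·s²)/(d₀+d) and the moderated t has d₀+d df (normal when d₀ is
infinite).  `prior_df=0` reproduces the ordinary t-test exactly (asserted
in the tests).  This is a reimplementation of the standard moderated-t
approach, not a wrapper; agreement with any particular package is not
claimed — calibration and planted-truth recovery are the contract.  FDR is
Benjamini–Hochberg.  logFC is high-group minus low-group mean on log2.

Signature construction runs a fresh moderated-DE round on a pre-selected
gene universe (first-round DEGs, with all samples re-included), then
searches a grid of (logFC_min, FDR_max) thresholds — default
{(0.89, 0.015), (1.12, 0.022)}, the two printed threshold pairs of the
source analysis — rather than arbitrary gene subsets: the grid is
reproducible and monotone.  Each candidate (the upregulated genes passing a
grid point) is scored per sample, scores are dichotomized at the
enrichment cutoff (default −0.05, fixed a priori and exposed as
configuration), and the Fisher P of the enriched × long-survivor table
(censored below the survival cutoff excluded) is minimized; ties prefer the
smaller signature.  Enrichment is computed on the full matrix
(`score_matrix`), not the DEG universe, since a set covering most of its
scoring matrix is uninformative.

## Single-sample enrichment scores

The expression-level statistic is the centered cross-sample rank of each
gene (rank − (n+1)/2), replacing the kernel-density ecdf of the published
method: only score ordering and the −0.05 dichotomization are consumed
downstream, and ranks preserve both while being exactly invariant under
monotone per-gene transforms.  Within each sample, genes are walked in
decreasing order of the statistic (gene index breaks ties
deterministically); set genes add |z|^τ normalized by the in-set total
(τ = 1), others subtract 1/(G−m).  The score is the maximum positive plus
the maximum negative deviation of the walk — the signed "difference of
extrema" convention — and both deviations are normalized by their
theoretical maxima, so scores are bounded in [−1, 1] and the −0.05 cutoff
lives on a fixed scale.  Sets retaining < 2 matrix genes are dropped with a
warning.  Note one non-property: adding a constant to a single sample's
expression vector *does* change that sample's scores (its cross-sample
ranks move by gene-dependent amounts); what is invariant is any per-gene
monotone transform, and Pearson cluster distances under per-sample shifts.

Subtype assignment takes the top-scoring set per sample, returning "nd"
when the top two scores are within `tie_margin` (default 0.01).  Clustering
is average-linkage (UPGMA) on 1 − Pearson correlation between samples;
zero-variance genes are dropped with a warning.

## Purity and deconvolution

Immune and stromal scores are enrichment scores of the two gene sets;
their sum maps to purity through a pluggable, strictly decreasing map.  The
default is an affine clamp calibrated on the cohort's observed score range
(lowest combined score → purity 1); an externally trained calibration can
be supplied instead — the published cosine calibration is not hard-coded
because its constants derive from another study's training data.  Relative
cell-type fractions come from non-negative least squares of the linearized
(2^x) expression on the reference profiles over shared genes, normalized to
sum to 1; NNLS replaces the published ν-SVR, with recovery on known
mixtures (not tool concordance) as the contract.  All-zero fits return
uniform fractions with a degenerate flag; rank-deficient references are
rejected naming the collinear columns.  Absolute fractions are
relative × (1 − purity), so fractions plus purity partition each sample;
the (1 − purity) multiplier is isolated in one function because the source
text does not print its exact correction formula.

## Synthetic cohorts

Defaults mirror the study conditions: 30 samples (76 for the cutpoint
experiments), hi_fraction 0.3, survival truncation at 1.8 years for the
high group (hazard 2.0/y, rejection-sampled below the horizon with a
retry cap), untruncated exponential (hazard 0.7/y) for the low group so
~26% survive past the horizon — the source cohort's long-survivor rate —
and administrative censoring (uniform follow-up limits, Cmax solved for a
15% target rate; the realized rate is recorded in the truth file).  Marker
H-scores are drawn group-separated (low on [10, 150], high on [180, 295]):
groups defined by a cutoff on observed values are separable by
construction, and within groups the marker is independent of survival.
Pixel-bin counts are synthesized per sample (20 000 pixels, Dirichlet bin
shapes rescaled to the target mean intensity) and regenerate the H-score to
< 0.1 units.  Expression is log2-normal (gene means U(4,10), noise sd 0.5)
with a planted 30-gene program (+1.5 log2 in the high group, applied after
admixture so the planted effect is exact).  The immune admixture mixes
cell-type reference profiles (10 marker genes per type, 16× elevated over
baseline) into each sample at 1 − purity, with purity drawn from
(0.4, 0.95) anti-correlated with the marker (ρ = 0.7).  A deliberate
consequence: the cell-type marker genes are genuinely differentially
expressed between high and low groups — as immune genes are in real
marker-high tumors — so signatures may legitimately absorb a few of them.

Not emulated: probe-level microarray noise, batch structure, realistic
censoring mechanisms, or tumor-intrinsic subtype programs.  Passing
recovery tests on these cohorts shows the procedures are correct and
calibrated under their stated assumptions, not that they are robust to
real-data artifacts.

## Problem sizes

The test and acceptance workloads use the generator defaults: 100 cohorts
of 76 for cutpoint recovery, 20 cohorts of 30 for signature recovery, 50
five-type mixtures for deconvolution, 1000-gene null matrices, 2000
log-rank null replicates and 500 null scans of 50 samples.

## Known limitations

* The scans are O(candidates × test); for cohorts far beyond ~10³ samples
  the Fisher-based scans would need an incremental table update.
* Dunn's pairwise P-values are unadjusted (the omnibus Kruskal–Wallis P is
  reported alongside); multiplicity control across pairs is the caller's
  choice.
* The purity map is cohort-relative by default: purities are comparable
  within a cohort, not across cohorts, unless a fixed calibration is
  supplied.
* Cox regression, proportional-hazards diagnostics and stratified models
  are intentionally absent (standard off-the-shelf statistics).
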