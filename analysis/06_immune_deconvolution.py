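"""Estimate purity, deconvolve cell-type fractions and correlate with the marker.

Immune/stromal enrichment scores give a per-sample purity estimate; NNLS on
the reference profiles gives relative fractions; purity correction turns
them into absolute fractions of each tumor, which are then correlated with
the IHC marker — the chain that links marker level to immune infiltration.
"""

import json

import pandas as pd

from gliostrat import deconvolution, io

expr = io.read_expression("results/cohort/expression.tsv")
reference = pd.read_csv("results/cohort/reference.tsv", sep="\t", index_col=0)
truth = json.load(open("results/cohort/truth.json"))
marker = pd.Series(truth["marker"])

ct = truth["cell_type_markers"]
types = list(ct)
immune = [g for t in types[:-1] for g in ct[t]]
stromal = ct[types[-1]]

scores = deconvolution.infiltrate_scores(expr, immune, stromal)
truth_purity = pd.Series(truth["purity"])
r_pur, _ = deconvolution.marker_fraction_correlation(scores["purity"], truth_purity)
print(f"estimated vs planted purity: r={r_pur:.2f}")

rel, degenerate = deconvolution.deconvolve(expr, reference)
absolute = deconvolution.purity_correct(rel, scores["purity"])
out = absolute.join(scores)
out.to_csv("results/cell_fractions.tsv", sep="\t", index_label="sample_id")

print(f"deconvolved {rel.shape[0]} samples into {rel.shape[1]} cell types "
      f"({int(degenerate.sum())} degenerate fits)")
print("marker correlation with purity-corrected fractions:")
for c in absolute.columns:
    r, p = deconvolution.marker_fraction_correlation(absolute[c], marker)
    print(f"  {c}: r={r:+.2f} (p={p:.3g})")
r, p = deconvolution.marker_fraction_correlation(1 - scores["purity"], marker)
print(f"  nontumor fraction: r={r:+.2f} (p={p:.3g})")
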