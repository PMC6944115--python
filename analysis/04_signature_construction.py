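"""Construct the prognostic signature from the stratified cohort.

First differential-expression round on the full matrix (marker-high vs low),
DEG selection, then the grid-searched second round whose candidate gene sets
are scored by sample-wise enrichment and judged by how well the dichotomized
scores separate marker-high tumors from long survivors.
"""

import json

import pandas as pd

from gliostrat import diffexpr, io, survival

expr = io.read_expression("results/cohort/expression.tsv")
clinical = survival.read_clinical("results/cohort/clinical.csv")
records = survival.records_from_frame(clinical)
strat = json.load(open("results/stratification.json"))["dual_fisher"]
groups = strat["labels"]
truth = json.load(open("results/cohort/truth.json"))

de = diffexpr.moderated_de(expr, groups)
de.to_csv("results/de_results.tsv", sep="\t", index_label="gene")
universe = diffexpr.select_degs(de, fdr_max=0.015, abs_lfc_min=0.89)
print(f"first DE round: {len(universe)} DEGs at FDR<0.015, |logFC|>=0.89 "
      f"(prior df {de.attrs['prior_df']:.1f})")

sig = diffexpr.build_signature(
    expr.loc[universe], groups, records,
    survival_cutoff=strat["survival_cutoff"],
    score_matrix=expr,
)
io.write_gmt({"signature": sig.genes}, "results/signature.gmt")
with open("results/signature.json", "w") as fh:
    json.dump({"genes": sig.genes, "thresholds_used": list(sig.thresholds_used),
               "separation_p": sig.separation_p, "table": sig.table}, fh, indent=1)

planted = set(truth["program_genes"])
got = set(sig.genes)
print(f"signature: {len(sig.genes)} genes at thresholds {sig.thresholds_used}, "
      f"separation p={sig.separation_p:.3g}")
print(f"Jaccard with planted program: {len(got & planted) / len(got | planted):.2f} "
      f"({len(got - planted)} extra genes, "
      f"{sum(g in {x for v in truth['cell_type_markers'].values() for x in v} for g in got - planted)}"
      " of them planted immune markers)")
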