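"""File formats, pipeline configuration and the end-to-end runner.

Formats are plain text throughout: expression matrices as TSV/CSV with genes
in rows and a header of sample ids, clinical tables as CSV, gene sets as
standard GMT (set name, description, tab-separated gene ids).  Gene and
sample identifiers are opaque case-sensitive strings; no symbol remapping is
attempted.

``run_pipeline`` ties the stages into the study's two workflows — marker →
stratification → survival, and expression → signature → enrichment →
deconvolution — and writes every output plus a manifest of SHA-256 hashes
and the effective configuration, so a run is reproducible from its own
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from gliostrat import deconvolution, diffexpr, enrichment, ihc, stratify, survival, synthetic

log = logging.getLogger("gliostrat")

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "PipelineConfig",
    "run_pipeline",
]


def read_expression(path, collapse_mapping: Optional[dict] = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix from delimited text.

    The first column holds gene identifiers, the header row sample ids.
    Duplicate gene rows are rejected unless ``collapse_mapping`` is given
    (then max-intensity collapsing is applied); duplicate sample ids and
    non-numeric cells are errors with context.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise ValueError(f"duplicate sample ids in {path.name}: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"non-numeric cells in columns {non_numeric} of {path.name}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"missing values in rows {bad} of {path.name}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        if collapse_mapping is None:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValueError(
                f"duplicate gene ids in {path.name} (e.g. {dups}); "
                "provide a collapse mapping to resolve them"
            )
        # make row keys unique before collapsing
        original = list(df.index)
        df.index = [f"row{i}" for i in range(len(original))]
        mapping = {
            f"row{i}": collapse_mapping.get(g, g) for i, g in enumerate(original)
        }
        df = diffexpr.collapse_genes(df, mapping)
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    matrix.to_csv(path, sep=sep, index_label="gene_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, tab-separated genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes: list[str] = []
        seen = set()
        for g in fields[2:]:
            if not g:
                continue
            if g in seen:
                log.warning("set %r lists gene %r more than once; deduplicated", name, g)
                continue
            seen.add(g)
            genes.append(g)
        if not genes:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run.

    With ``simulate=True`` the inputs are generated by the synthetic-cohort
    module under ``seed``; otherwise the file paths are read.  Stage
    parameters default to the study's values.
    """

    out_dir: str = "run"
    simulate: bool = True
    seed: int = 0
    clinical_path: Optional[str] = None
    pixel_counts_path: Optional[str] = None
    expression_path: Optional[str] = None
    gmt_path: Optional[str] = None
    reference_path: Optional[str] = None
    marker_name: str = "marker"
    min_group_fraction: float = 0.1
    balance_weight: float = 1.0
    median_diff_weight: float = 1.0
    deg_fdr_max: float = 0.015
    deg_abs_lfc_min: float = 0.89
    signature_grid: list = field(default_factory=lambda: [[0.89, 0.015], [1.12, 0.022]])
    enrichment_cutoff: float = -0.05
    n_samples: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Log stage boundaries and re-raise failures with the stage name."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the stages in dependency order and write a provenance manifest.

    Returns the run directory.  Any stage error aborts with the stage name;
    nothing is written past a failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    with _stage("inputs"):
        if config.simulate:
            cohort = synthetic.generate_cohort(
                synthetic.CohortConfig(seed=config.seed, n_samples=config.n_samples)
            )
            paths = synthetic.write_cohort(cohort, out / "inputs")
            outputs.update({f"input_{k}": v for k, v in paths.items()})
            clinical = cohort.clinical
            pixel_rows = ihc.read_pixel_counts(paths["pixel_counts"])
            expr = cohort.expression
            reference = cohort.reference
            gene_sets = {
                c: genes for c, genes in cohort.truth["cell_type_markers"].items()
            }
        else:
            for name in ("clinical_path", "pixel_counts_path", "expression_path"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input {name} missing: {p}")
            clinical = survival.read_clinical(config.clinical_path)
            pixel_rows = ihc.read_pixel_counts(config.pixel_counts_path)
            expr = read_expression(config.expression_path)
            reference = (
                pd.read_csv(config.reference_path, sep="\t", index_col=0)
                if config.reference_path
                else None
            )
            gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None

    with _stage("ihc_quantification"):
        scores = ihc.score_table(pixel_rows)
        ihc.write_marker_scores(scores, out / "marker_scores.csv")
        outputs["marker_scores"] = out / "marker_scores.csv"
        marker_values = {
            s.sample_id: s.value for s in scores if s.kind == "hscore"
        }

    with _stage("stratification"):
        records = survival.records_from_frame(clinical)
        constraints = stratify.ScanConstraints(
            config.min_group_fraction, config.balance_weight, config.median_diff_weight
        )
        strat = stratify.dual_cutoff_fisher_scan(
            marker_values, records, constraints, marker=config.marker_name
        )
        (out / "stratification.json").write_text(
            json.dumps(strat.to_dict(), indent=1, sort_keys=True, default=str)
        )
        outputs["stratification"] = out / "stratification.json"

    with _stage("differential_expression"):
        de = diffexpr.moderated_de(expr, strat.labels)
        de.to_csv(out / "de_results.tsv", sep="\t", index_label="gene")
        outputs["de_results"] = out / "de_results.tsv"
        universe = diffexpr.select_degs(
            de, fdr_max=config.deg_fdr_max, abs_lfc_min=config.deg_abs_lfc_min
        )

    with _stage("signature"):
        if len(universe) >= 2:
            sig = diffexpr.build_signature(
                expr.loc[universe],
                strat.labels,
                records,
                survival_cutoff=strat.survival_cutoff,
                grid=[tuple(g) for g in config.signature_grid],
                enrichment_cutoff=config.enrichment_cutoff,
                score_matrix=expr,
            )
            sig_payload = {
                "genes": sig.genes,
                "thresholds_used": list(sig.thresholds_used),
                "separation_p": sig.separation_p,
                "enrichment_cutoff": sig.enrichment_cutoff,
                "table": sig.table,
            }
            write_gmt({"signature": sig.genes}, out / "signature.gmt")
            outputs["signature_gmt"] = out / "signature.gmt"
        else:
            sig_payload = {"genes": [], "note": "fewer than 2 DEGs; signature skipped"}
        (out / "signature.json").write_text(json.dumps(sig_payload, indent=1, sort_keys=True))
        outputs["signature"] = out / "signature.json"

    with _stage("enrichment"):
        if gene_sets:
            usable = {
                n: g for n, g in gene_sets.items()
                if len(set(g) & set(expr.index)) >= 2
            }
            if usable:
                scores_m = enrichment.sample_enrichment_scores(expr, usable)
                scores_m.to_csv(out / "enrichment_scores.tsv", sep="\t", index_label="set")
                outputs["enrichment_scores"] = out / "enrichment_scores.tsv"

    with _stage("deconvolution"):
        if reference is not None:
            fracs, _ = deconvolution.deconvolve(expr, reference)
            fracs.to_csv(out / "cell_fractions.tsv", sep="\t", index_label="sample_id")
            outputs["cell_fractions"] = out / "cell_fractions.tsv"

    manifest = {
        "config": config.to_dict(),
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
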