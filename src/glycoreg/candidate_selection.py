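"""Combine the three evidence criteria and the anabolic/catabolic filter,
and orchestrate the full candidate-discovery phase.

The final candidate set is (c1 union c2 union c3) intersected with the
catalog genes flagged anabolic or catabolic (criterion 4). The pipeline
runs, per dataset: moderated-t differential expression with two contrasts,
concordance filtering and cross-dataset intersection (criterion 1),
ensemble gene-set enrichment with direction concordance (criterion 2), and
repeated graph-regularized logistic models (criterion 3); every stage's
table is written to the output directory with a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import differential_expression as de_mod
from . import pathway_enrichment as enr_mod
from . import network_predictor as net_mod
from .io_formats import GeneCatalog, GeneSetCollection
from .synthetic_data import OmicsCohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineThresholds:
    de_fdr: float = 0.05
    enrich_fdr: float = 0.05
    top_fraction: float = 0.5
    n_models: int = 10
    min_datasets: int = 2  # predictive-gene rule


def apply_criteria(
    c1_genes: set[str] | dict[str, str],
    c2_genes: set[str] | list[str],
    c3_genes: set[str] | list[str],
    catalog: GeneCatalog,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene criterion flags and the final selection.

    final_selected = (c1 or c2 or c3) and is_anabolic_or_catabolic. Any
    gene outside the catalog is a hard error naming the gene.
    """
    c1, c2, c3 = set(c1_genes), set(c2_genes), set(c3_genes)
    union = c1 | c2 | c3
    for g in sorted(union):
        if g not in catalog:
            raise KeyError(f"gene {g!r} is not in the glycogene catalog")
    directions = directions or (c1_genes if isinstance(c1_genes, dict) else {})
    rows = []
    for g in sorted(union):
        c4 = catalog.is_flagged(g)
        rows.append({
            "gene": g,
            "c1": g in c1,
            "c2": g in c2,
            "c3": g in c3,
            "c4": c4,
            "direction": directions.get(g, ""),
            "pathways": ";".join(sorted(catalog.pathways_of(g))),
            "final_selected": c4,  # union membership is given; c4 decides
        })
    return pd.DataFrame(rows, columns=["gene", "c1", "c2", "c3", "c4",
                                       "direction", "pathways", "final_selected"])


@dataclass
class PipelineResult:
    de_tables: list[pd.DataFrame]
    c1_genes: list[str]
    common_de: dict[str, str]
    enrichment_tables: list[pd.DataFrame]
    enriched_sets: dict[str, str]
    c2_genes: list[str]
    selection_summaries: list[net_mod.SelectionSummary]
    c3_genes: list[str]
    report: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def final_genes(self) -> list[str]:
        return self.report.loc[self.report["final_selected"], "gene"].tolist()


def run_pipeline(
    cohorts: list[OmicsCohort],
    gene_sets: GeneSetCollection,
    catalog: GeneCatalog,
    out_dir: str | Path | None = None,
    seed: int = 0,
    thresholds: PipelineThresholds | None = None,
) -> PipelineResult:
    """Run criteria 1-4 over the cohorts and (optionally) write all stages.

    Deterministic given ``seed``. Errors raised inside a stage are
    re-raised with the stage name attached.
    """
    th = thresholds or PipelineThresholds()
    stage = "differential_expression"
    try:
        de_tables = []
        concordant = []
        for cohort in cohorts:
            table = de_mod.de_table(cohort.expression, cohort.samples)
            de_tables.append(table)
            concordant.append(de_mod.concordant_de(table, fdr_threshold=th.de_fdr))
        common = de_mod.cross_dataset_intersection(concordant)
        c1 = de_mod.top_half(common, de_tables) if common else []

        stage = "pathway_enrichment"
        enr_tables = [enr_mod.enrich_dataset(t, gene_sets, de_fdr=th.de_fdr)
                      for t in de_tables]
        enriched = enr_mod.concordant_enriched_sets(enr_tables, fdr=th.enrich_fdr)
        c2 = enr_mod.criterion2_genes(enriched, gene_sets, de_tables) if enriched else []

        stage = "network_predictor"
        graph_sets = (GeneSetCollection({k: gene_sets[k] for k in enriched})
                      if enriched else gene_sets)
        graph = net_mod.build_graph(graph_sets)
        summaries = []
        for cohort in cohorts:
            group = cohort.samples.group_of()
            keep = [s for s in cohort.expression.samples
                    if group.get(s) in ("TNBC", "non-TNBC")]
            X = cohort.expression.values[keep].T
            y = group.loc[keep]
            summaries.append(net_mod.repeated_models(
                X, y, graph, dataset_id=cohort.expression.dataset_id,
                n_models=th.n_models, seed=seed,
            ))
        c3 = net_mod.predictive_gene_rule(summaries, min_datasets=th.min_datasets)

        stage = "candidate_selection"
        report = apply_criteria(set(c1), set(c2), set(c3), catalog, directions=common)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(
        de_tables=de_tables, c1_genes=list(c1), common_de=common,
        enrichment_tables=enr_tables, enriched_sets=enriched, c2_genes=list(c2),
        selection_summaries=summaries, c3_genes=list(c3), report=report,
    )
    if out_dir is not None:
        result.manifest = _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        files[name.removesuffix(".tsv")] = name

    save("de_tables.tsv", pd.concat(result.de_tables, ignore_index=True))
    save("criterion1_genes.tsv", pd.DataFrame({"gene": sorted(result.c1_genes)}))
    save("enrichment_tables.tsv",
         pd.concat(result.enrichment_tables, ignore_index=True)
         if result.enrichment_tables else pd.DataFrame())
    save("criterion2_genes.tsv", pd.DataFrame({"gene": sorted(result.c2_genes)}))
    counts = pd.concat(
        [s.counts.rename(s.dataset_id) for s in result.selection_summaries], axis=1
    ).reset_index(names="gene")
    save("selection_summary.tsv", counts)
    save("criterion3_genes.tsv", pd.DataFrame({"gene": sorted(result.c3_genes)}))
    save("candidate_report.tsv", result.report)
    manifest = {"stages": files, "n_stage_outputs": len(files)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
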