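"""Synthetic multi-cohort multi-omic data with planted ground truth.

The generator emulates the structure of three independent breast-cancer
expression cohorts (one TCGA-like, two METABRIC-like) sharing a common
biological truth but with independent noise: planted differentially
expressed genes, pathway-coherent expression shifts, genes driven in cis by
copy number (positive coupling) or DNA methylation (negative coupling), and
TF-driven genes whose regulatory edges may be specific to the TNBC group.

Generative model for gene g in sample s of a given group:

    expr(g, s) = mu_g + delta_g * 1[s in TNBC] + alpha_g * cna(g, s)
                 + beta_g * dm(g, s) + sum_t w(t, g, group) * tf(t, s)
                 + eps,   eps ~ Normal(0, noise_sd^2)

CNA values are Normal copy ratios (with a TNBC-specific mean shift for
CNA-driven genes); DM beta values are logistic-transformed Gaussians and
always lie in (0, 1); beta_g < 0 for DM-driven genes so that methylation
represses expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    GenomicIntervalSet,
    SampleTable,
    TSSTable,
    catalog_from_records,
    GeneCatalog,
)

GENE_SPACING = 10_000  # bp between successive TSSs on the toy contig
TOY_CHROM = "chr1"


@dataclass
class PlantedPathway:
    """A gene set whose members share a planted expression shift."""

    name: str
    size: int
    direction: int  # +1 up in TNBC, -1 down
    effect: float  # |log2FC| applied to every member


@dataclass
class SimulationConfig:
    n_genes: int = 120
    n_tfs: int = 25
    n_per_group: int = 150  # samples per group per cohort
    n_cohorts: int = 3
    de_fraction: float = 0.1
    de_effect: float = 2.0  # log2FC of planted DE genes
    planted_pathways: list[PlantedPathway] = dc_field(default_factory=list)
    n_null_sets: int = 20
    null_set_size: int = 8
    n_cna_driven: int = 10
    cna_alpha: float = 1.0  # expression units per copy-ratio unit
    cna_sd: float = 0.5
    cna_tnbc_shift: float = 0.5
    n_dm_driven: int = 10
    dm_beta: float = -2.0  # must be negative: methylation represses
    n_tnbc_only_edges: int = 10
    n_shared_edges: int = 10
    edges_per_tf: int = 1  # consecutive planted edges sharing one TF
    tf_weight: float = 1.0
    tf_correlation: float = 0.0  # optional TF-TF correlation
    noise_sd: float = 1.0
    anabolic_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tfs, self.n_per_group, self.n_cohorts) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not np.isfinite(self.de_effect):
            raise ValueError("de_effect must be finite")
        if self.dm_beta > 0:
            raise ValueError("dm_beta must be <= 0: methylation represses expression")


@dataclass
class OmicsCohort:
    """One cohort's layers sharing a sample index."""

    expression: ExpressionMatrix
    cna: pd.DataFrame
    dm: pd.DataFrame
    tf_expression: pd.DataFrame
    samples: SampleTable
    peaks: GenomicIntervalSet | None = None
    tss: TSSTable | None = None

    def __post_init__(self) -> None:
        cols = list(self.expression.values.columns)
        for name, layer in (("cna", self.cna), ("dm", self.dm),
                            ("tf_expression", self.tf_expression)):
            if list(layer.columns) != cols:
                raise ValueError(f"{name} layer does not share the sample index")
        dm = self.dm.to_numpy()
        if dm.size and (dm.min() < 0 or dm.max() > 1):
            raise ValueError("DM beta values must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted effects, for recovery tests."""

    de_genes: dict[str, int]  # gene -> +1/-1
    enriched_pathways: dict[str, int]  # set name -> +1/-1
    cna_driven: list[str]
    dm_driven: list[str]
    tf_edges: dict[str, set[tuple[str, str]]]  # group -> {(tf, gene)}
    tf_weights: dict[tuple[str, str, str], float]  # (tf, gene, group) -> w
    gene_sets: GeneSetCollection | None = None
    catalog: GeneCatalog | None = None


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _tf_names(n: int) -> list[str]:
    return [f"TF{i:03d}" for i in range(n)]


def make_tss_table(genes: list[str], spacing: int = GENE_SPACING) -> TSSTable:
    """Lay genes along a toy contig, one TSS every ``spacing`` bp."""
    df = pd.DataFrame(
        {
            "gene": genes,
            "chrom": TOY_CHROM,
            "tss": [spacing * (i + 1) for i in range(len(genes))],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(len(genes))],
        }
    )
    return TSSTable(df)


def _plan_truth(config: SimulationConfig, rng: np.random.Generator):
    """Allocate disjoint gene blocks to the planted effect classes."""
    genes = _gene_names(config.n_genes)
    tfs = _tf_names(config.n_tfs)

    n_de = int(round(config.de_fraction * config.n_genes))
    n_pathway = sum(p.size for p in config.planted_pathways)
    cursor = 0

    def take(k: int, label: str) -> list[str]:
        nonlocal cursor
        if cursor + k > config.n_genes:
            raise ValueError(
                f"config requests more driven genes than n_genes "
                f"(ran out while allocating {label})"
            )
        block = genes[cursor:cursor + k]
        cursor += k
        return block

    de_block = take(n_de, "de_genes")
    de_genes = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(de_block)}

    pathway_members: dict[str, list[str]] = {}
    enriched: dict[str, int] = {}
    for p in config.planted_pathways:
        members = take(p.size, f"pathway {p.name}")
        pathway_members[p.name] = members
        enriched[p.name] = p.direction

    cna_driven = take(config.n_cna_driven, "cna_driven")
    dm_driven = take(config.n_dm_driven, "dm_driven")

    tf_target_genes = take(
        min(config.n_tnbc_only_edges + config.n_shared_edges,
            config.n_genes - cursor),
        "tf targets",
    )

    # TNBC-only edges use the first TFs, shared edges the next ones; targets
    # cycle over the allocated block so several edges can share a gene.
    tf_edges: dict[str, set[tuple[str, str]]] = {"TNBC": set(), "non-TNBC": set()}
    tf_weights: dict[tuple[str, str, str], float] = {}
    k = max(config.edges_per_tf, 1)
    if tf_target_genes:
        for i in range(config.n_tnbc_only_edges):
            tf = tfs[(i // k) % config.n_tfs]
            g = tf_target_genes[i % len(tf_target_genes)]
            tf_edges["TNBC"].add((tf, g))
            tf_weights[(tf, g, "TNBC")] = config.tf_weight
        for i in range(config.n_shared_edges):
            tf = tfs[((config.n_tnbc_only_edges + i) // k) % config.n_tfs]
            g = tf_target_genes[(config.n_tnbc_only_edges + i) % len(tf_target_genes)]
            for grp in ("TNBC", "non-TNBC"):
                tf_edges[grp].add((tf, g))
                tf_weights[(tf, g, grp)] = config.tf_weight

    # Gene sets: one per planted pathway plus random null sets.
    sets: dict[str, list[str]] = dict(pathway_members)
    for j in range(config.n_null_sets):
        members = list(rng.choice(genes, size=min(config.null_set_size, config.n_genes),
                                  replace=False))
        sets[f"null_set_{j:03d}"] = members
    collection = GeneSetCollection(sets) if sets else GeneSetCollection({"all": genes})

    # Catalog: pathway membership from the gene sets; anabolic/catabolic flag
    # assigned deterministically from the rng.
    flags = rng.random(config.n_genes) < config.anabolic_fraction
    membership: dict[str, set[str]] = {g: set() for g in genes}
    for name, members in sets.items():
        for g in members:
            membership[g].add(name)
    catalog = catalog_from_records(
        (g, membership[g], bool(flags[i])) for i, g in enumerate(genes)
    )

    truth = SyntheticTruth(
        de_genes=de_genes,
        enriched_pathways=enriched,
        cna_driven=list(cna_driven),
        dm_driven=list(dm_driven),
        tf_edges=tf_edges,
        tf_weights=tf_weights,
        gene_sets=collection,
        catalog=catalog,
    )
    pathway_effects = {
        g: p.direction * p.effect
        for p in config.planted_pathways
        for g in pathway_members[p.name]
    }
    return genes, tfs, truth, pathway_effects


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[OmicsCohort], SyntheticTruth]:
    """Generate ``config.n_cohorts`` cohorts sharing one planted truth.

    Deterministic given ``config.seed``; cohorts differ only in their noise
    and sample-level draws.
    """
    master = np.random.default_rng(config.seed)
    genes, tfs, truth, pathway_effects = _plan_truth(config, master)
    n = config.n_per_group

    mu = master.normal(8.0, 1.0, size=config.n_genes)  # baseline log2 expression
    dm_logit_mu = master.normal(0.0, 1.0, size=config.n_genes)

    delta = np.zeros(config.n_genes)
    alpha = np.zeros(config.n_genes)
    beta = np.zeros(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, d in truth.de_genes.items():
        delta[gene_index[g]] = d * config.de_effect
    for g, eff in pathway_effects.items():
        delta[gene_index[g]] = eff
    for g in truth.cna_driven:
        alpha[gene_index[g]] = config.cna_alpha
    for g in truth.dm_driven:
        beta[gene_index[g]] = config.dm_beta

    groups = ["TNBC"] * n + ["non-TNBC"] * n + ["normal"] * n
    is_tnbc = np.array([g == "TNBC" for g in groups], dtype=float)

    tss = make_tss_table(genes)
    cohorts: list[OmicsCohort] = []
    for c in range(config.n_cohorts):
        rng = np.random.default_rng([config.seed, c])
        dataset_id = f"D{c + 1}"
        sample_ids = [f"{dataset_id}_{grp}_{i:03d}" for i, grp in enumerate(groups)]
        n_samples = len(sample_ids)

        cna = rng.normal(0.0, config.cna_sd, size=(config.n_genes, n_samples))
        for g in truth.cna_driven:
            cna[gene_index[g]] += config.cna_tnbc_shift * is_tnbc
        dm = 1.0 / (1.0 + np.exp(-(dm_logit_mu[:, None]
                                   + rng.normal(0.0, 1.0, size=(config.n_genes, n_samples)))))

        if config.tf_correlation > 0:
            shared = rng.normal(0.0, 1.0, size=n_samples)
            tf_expr = (np.sqrt(config.tf_correlation) * shared
                       + np.sqrt(1 - config.tf_correlation)
                       * rng.normal(0.0, 1.0, size=(config.n_tfs, n_samples)))
        else:
            tf_expr = rng.normal(0.0, 1.0, size=(config.n_tfs, n_samples))
        tf_index = {t: i for i, t in enumerate(tfs)}

        expr = (mu[:, None]
                + delta[:, None] * is_tnbc[None, :]
                + alpha[:, None] * cna
                + beta[:, None] * dm)
        group_arr = np.array(groups)
        for (tf, g, grp), w in truth.tf_weights.items():
            mask = (group_arr == grp).astype(float)
            expr[gene_index[g]] += w * tf_expr[tf_index[tf]] * mask
        if config.noise_sd > 0:
            expr = expr + rng.normal(0.0, config.noise_sd,
                                     size=(config.n_genes, n_samples))

        samples = SampleTable(pd.DataFrame({
            "sample_id": sample_ids,
            "group": groups,
            "dataset_id": dataset_id,
        }))
        cohorts.append(OmicsCohort(
            expression=ExpressionMatrix(
                pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                             columns=sample_ids),
                dataset_id=dataset_id,
            ),
            cna=pd.DataFrame(cna, index=pd.Index(genes, name="gene"),
                             columns=sample_ids),
            dm=pd.DataFrame(dm, index=pd.Index(genes, name="gene"),
                            columns=sample_ids),
            tf_expression=pd.DataFrame(tf_expr, index=pd.Index(tfs, name="tf"),
                                       columns=sample_ids),
            samples=samples,
            tss=tss,
        ))
    return cohorts, truth


def make_binding_peaks(
    truth: SyntheticTruth,
    tss: TSSTable,
    decoy_rate: float = 0.0,
    seed: int = 0,
    window: int = 2000,
) -> GenomicIntervalSet:
    """ChIP-evidence peaks consistent with the planted TF edges.

    Every true TF-gene edge (either group) receives one peak whose midpoint
    lies within ``window`` bp of the target's TSS. ``decoy_rate`` decoy
    peaks per true edge are added: half bind promoters of non-target genes
    (non-functional binding), half fall between promoter windows.
    """
    rng = np.random.default_rng(seed)
    all_edges = sorted(set().union(*truth.tf_edges.values()))
    tss_pos = dict(zip(tss.table["gene"], tss.table["tss"]))
    all_genes = list(tss.table["gene"])
    tfs = sorted({t for t, _ in all_edges}) or ["TF000"]

    rows = []
    half_width = 50
    for tf, gene in all_edges:
        if gene not in tss_pos:
            raise KeyError(f"gene {gene!r} absent from TSS table")
        center = tss_pos[gene] + int(rng.integers(-window + half_width,
                                                  window - half_width + 1))
        rows.append((TOY_CHROM, center - half_width, center + half_width, tf))

    n_decoys = int(round(decoy_rate * len(all_edges)))
    for j in range(n_decoys):
        tf = tfs[int(rng.integers(len(tfs)))]
        if j % 2 == 0:  # non-functional promoter binding
            gene = all_genes[int(rng.integers(len(all_genes)))]
            center = tss_pos[gene] + int(rng.integers(-window + half_width,
                                                      window - half_width + 1))
        else:  # intergenic, outside every promoter window
            gene = all_genes[int(rng.integers(len(all_genes)))]
            center = tss_pos[gene] + GENE_SPACING // 2
        rows.append((TOY_CHROM, center - half_width, center + half_width, tf))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])
    return GenomicIntervalSet(df)
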