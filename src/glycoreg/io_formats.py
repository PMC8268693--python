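"""Readers, writers and the shared data model.

All tabular formats are plain TSV; gene sets are GMT; ChIP peaks are BED4
(0-based half-open, name column = TF). Gene identifiers are plain symbols,
case-sensitive, with no aliasing. Missing expression values are carried as
NaN, never silently imputed to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("TNBC", "non-TNBC", "normal")
VALID_STRANDS = ("+", "-")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneCatalog:
    """Catalog of glycosylation genes with pathway membership and an
    anabolic/catabolic flag.

    ``table`` is indexed by unique gene symbol with columns
    ``pathways`` (frozenset of pathway names) and
    ``is_anabolic_or_catabolic`` (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols in catalog: {dups}")
        for sym, pws in self.table["pathways"].items():
            if any(not p for p in pws):
                raise FormatError(f"empty pathway name for gene {sym!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def is_flagged(self, gene: str) -> bool:
        return bool(self.table.at[gene, "is_anabolic_or_catabolic"])

    def pathways_of(self, gene: str) -> frozenset[str]:
        return self.table.at[gene, "pathways"]

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log2-scale expression values.

    ``values``: DataFrame indexed by unique gene symbols, columns unique
    sample IDs; missing measurements are NaN.
    """

    values: pd.DataFrame
    dataset_id: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise FormatError("expression matrix contains infinite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def drop_sparse_genes(self, max_missing_frac: float = 0.2) -> "ExpressionMatrix":
        """Drop genes with more than ``max_missing_frac`` missing samples."""
        frac = self.values.isna().mean(axis=1)
        bad = frac[frac > max_missing_frac].index
        if len(bad):
            logger.warning(
                "dataset %s: dropping %d genes with >%d%% missing values",
                self.dataset_id, len(bad), int(100 * max_missing_frac),
            )
        return ExpressionMatrix(self.values.drop(index=bad), self.dataset_id)


@dataclass
class SampleTable:
    """Sample metadata: one row per sample with its group label."""

    table: pd.DataFrame  # columns: sample_id, group, dataset_id

    def __post_init__(self) -> None:
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample IDs in sample table: {dups}")
        bad = set(self.table["group"]) - set(VALID_GROUPS)
        if bad:
            raise FormatError(
                f"unknown sample groups {sorted(bad)}; allowed: {list(VALID_GROUPS)}"
            )

    def samples_in_group(self, group: str) -> list[str]:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}; allowed: {list(VALID_GROUPS)}")
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> ordered member list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class GenomicIntervalSet:
    """ChIP peak intervals, 0-based half-open, name column = TF."""

    table: pd.DataFrame  # columns: chrom, start, end, tf

    def __post_init__(self) -> None:
        t = self.table
        bad = t.index[(t["start"] >= t["end"]) | (t["chrom"] == "")]
        if len(bad):
            i = int(bad[0])
            raise FormatError(
                f"invalid interval at record {i}: "
                f"{t.loc[i, 'chrom']}:{t.loc[i, 'start']}-{t.loc[i, 'end']}"
            )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TSSTable:
    """Transcription start sites, 0-based coordinates."""

    table: pd.DataFrame  # columns: gene, chrom, tss, strand

    def __post_init__(self) -> None:
        if self.table["gene"].duplicated().any():
            dups = self.table.loc[self.table["gene"].duplicated(), "gene"].tolist()
            raise FormatError(f"duplicate TSS rows for genes: {dups}")
        bad = set(self.table["strand"]) - set(VALID_STRANDS)
        if bad:
            raise FormatError(
                f"invalid strand values {sorted(bad)}; allowed strands: {list(VALID_STRANDS)}"
            )

    def position_of(self, gene: str) -> tuple[str, int]:
        row = self.table.loc[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} absent from TSS table")
        return str(row.iloc[0]["chrom"]), int(row.iloc[0]["tss"])


@dataclass
class BipartiteNetwork:
    """TF -> gene edges with stability-selection frequencies, per group."""

    edges: pd.DataFrame  # columns: tf, gene, frequency
    group_label: str

    def __post_init__(self) -> None:
        e = self.edges
        if e.duplicated(subset=["tf", "gene"]).any():
            dups = e.loc[e.duplicated(subset=["tf", "gene"]), ["tf", "gene"]]
            raise FormatError(f"duplicate (tf, gene) pairs: {dups.values.tolist()}")
        f = e["frequency"].to_numpy(dtype=float)
        if len(f) and (np.nanmin(f) < 0 or np.nanmax(f) > 1):
            raise FormatError("selection frequencies must lie in [0, 1]")

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["gene"]))

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _check_rectangular(path: Path) -> int:
    """Verify every TSV row has the same field count; return that count."""
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = n
            elif n != width:
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({n} fields, expected {width})"
                )
    if width is None:
        raise FormatError(f"{path}: empty file")
    return width


def read_expression_matrix(path: str | Path, dataset_id: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample IDs, first column = gene).

    "NA" or empty cells become missing values (NaN). Duplicate gene symbols
    and ragged rows are hard errors.
    """
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df = df.astype(float)
    df.index.name = "gene"
    return ExpressionMatrix(df, dataset_id=dataset_id)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a plain genes x samples TSV layer (CNA, DM, TF expression)."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"]).astype(float)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row identifiers: {dups}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "dataset_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing sample-table columns {sorted(missing)}")
    return SampleTable(df[["sample_id", "group", "dataset_id"]])


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read GMT: name, description, then tab-separated member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one member gene"
                )
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            if not members:
                raise FormatError(f"{path}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_peaks(path: str | Path) -> GenomicIntervalSet:
    """Read BED4 peaks (chrom, start, end, TF name), 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: BED4 needs chrom, start, end, name")
            chrom, start, end, tf = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise FormatError(
                    f"{path}: record {len(rows)} (line {lineno}): start {start} >= end {end}"
                )
            rows.append((chrom, start, end, tf))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])
    return GenomicIntervalSet(df)


def write_peaks(peaks: GenomicIntervalSet, path: str | Path) -> None:
    peaks.table.to_csv(path, sep="\t", header=False, index=False)


def read_tss(path: str | Path) -> TSSTable:
    """Read a 4-column TSS TSV: gene, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing TSS columns {sorted(missing)}")
    df["tss"] = df["tss"].astype(int)
    return TSSTable(df[["gene", "chrom", "tss", "strand"]])


def write_tss(tss: TSSTable, path: str | Path) -> None:
    tss.table.to_csv(path, sep="\t", index=False)


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read the glycogene catalog TSV.

    Columns: gene, pathways (semicolon-separated), anabolic_or_catabolic
    (true/false).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "pathways", "anabolic_or_catabolic"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing catalog columns {sorted(missing)}")
    table = pd.DataFrame(
        {
            "pathways": [
                frozenset(p for p in str(x).split(";") if p != "nan" and x == x)
                if x == x else frozenset()
                for x in df["pathways"]
            ],
            "is_anabolic_or_catabolic": df["anabolic_or_catabolic"]
            .str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
            .to_numpy(),
        },
        index=pd.Index(df["gene"], name="gene"),
    )
    if table["is_anabolic_or_catabolic"].isna().any():
        raise FormatError(f"{path}: anabolic_or_catabolic must be true/false")
    return GeneCatalog(table)


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "gene": catalog.table.index,
            "pathways": [";".join(sorted(p)) for p in catalog.table["pathways"]],
            "anabolic_or_catabolic": [
                str(bool(v)).lower() for v in catalog.table["is_anabolic_or_catabolic"]
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> BipartiteNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene": str, "group": str})
    if df.empty:
        return BipartiteNetwork(
            pd.DataFrame(columns=["tf", "gene", "frequency"]), group_label=""
        )
    group = df["group"].iloc[0]
    return BipartiteNetwork(df[["tf", "gene", "frequency"]].copy(), group_label=group)


def write_edge_list(network: BipartiteNetwork, path: str | Path) -> None:
    out = network.edges.copy()
    out["group"] = network.group_label
    out.to_csv(path, sep="\t", index=False, columns=["tf", "gene", "frequency", "group"])


def catalog_from_records(
    records: Iterable[tuple[str, Iterable[str], bool]]
) -> GeneCatalog:
    """Build a GeneCatalog from (gene, pathways, is_anabolic_or_catabolic)."""
    genes, pws, flags = [], [], []
    for g, p, f in records:
        genes.append(g)
        pws.append(frozenset(p))
        flags.append(bool(f))
    table = pd.DataFrame(
        {"pathways": pws, "is_anabolic_or_catabolic": flags},
        index=pd.Index(genes, name="gene"),
    )
    return GeneCatalog(table)
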