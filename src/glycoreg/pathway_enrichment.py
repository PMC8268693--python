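"""Criterion two: ensemble gene-set enrichment with direction concordance.

Two base methods are combined per gene set — an exact hypergeometric
over-representation test on the significant-gene list, and a two-sided
rank-sum test of member-gene moderated-t statistics against non-members —
with mean-rank aggregation and Fisher combination of p-values. A set's
direction is the sign of the mean moderated t of its member genes. Sets
must be significant (BH FDR < threshold) with the same direction in both
contrasts of every dataset; genes are then pulled from the enriched sets
when their own differential-expression direction matches the set's.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_MEMBERS = 10


def ora_test(de_genes: set[str], gene_set: set[str], universe: set[str]) -> float:
    """Exact hypergeometric over-representation tail probability.

    p = P(X >= k) with X ~ Hypergeometric(N=|universe|, K=|gene_set|,
    n=|de_genes|), k the observed overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    N, K, n = len(universe), len(gene_set), len(de_genes)
    k = len(de_genes & gene_set)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def rank_test(
    t_stats: pd.Series, gene_set: set[str]
) -> tuple[float, str | None]:
    """Two-sided rank-sum test of member-gene t statistics vs non-members.

    Exact null (full enumeration) for <= 10 members; normal approximation
    with tie correction otherwise. Direction is the sign of the mean member
    t; ``None`` when undefined (all statistics identical).
    """
    members = t_stats[t_stats.index.isin(gene_set)].dropna()
    others = t_stats[~t_stats.index.isin(gene_set)].dropna()
    if len(members) < 1 or len(others) < 1:
        raise ValueError("rank test needs at least one member and one non-member")
    if t_stats.dropna().nunique() == 1:
        return 1.0, None
    method = "exact" if (len(members) <= EXACT_RANKSUM_MAX_MEMBERS
                         and len(np.unique(t_stats.dropna())) == len(t_stats.dropna())) \
        else "asymptotic"
    res = stats.mannwhitneyu(members, others, alternative="two-sided", method=method)
    direction = "up" if members.mean() > 0 else "down"
    return float(res.pvalue), direction


def fisher_combine(pvalues: np.ndarray) -> float:
    """Fisher's method: chi-square upper tail of -2 sum(log p) on 2m df."""
    p = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0)
    statistic = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(statistic, 2 * len(p)))


def ensemble_combine(
    per_method_p: pd.DataFrame, per_method_rank: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Aggregate base-method results per gene set.

    ``per_method_p``: sets x methods p-values. Ranks (1 = most significant,
    computed within each method unless supplied) are averaged into the
    ensemble rank; p-values are combined with Fisher's method. Sets missing
    any base method are excluded and logged.
    """
    if per_method_p.shape[1] < 2:
        raise ValueError("ensemble requires at least 2 base methods")
    complete = per_method_p.dropna()
    dropped = set(per_method_p.index) - set(complete.index)
    if dropped:
        logger.warning("sets excluded from ensemble (missing a base method): %s",
                       sorted(dropped))
    if per_method_rank is None:
        per_method_rank = complete.rank(axis=0, method="average")
    else:
        per_method_rank = per_method_rank.loc[complete.index]
    out = pd.DataFrame(index=complete.index)
    out["ensemble_rank"] = per_method_rank.mean(axis=1)
    out["p_combined"] = [fisher_combine(row.to_numpy()) for _, row in complete.iterrows()]
    return out


def enrich_dataset(
    de: pd.DataFrame,
    gene_sets: GeneSetCollection,
    universe: set[str] | None = None,
    de_fdr: float = 0.05,
) -> pd.DataFrame:
    """Ensemble enrichment for one dataset's DE table (both contrasts).

    Returns one row per (set, contrast): base p-values, ensemble rank,
    Fisher-combined p, BH FDR across sets within the contrast, and
    direction (sign of mean member moderated t).
    """
    rows = []
    for contrast, sub in de.groupby("contrast"):
        sub = sub.set_index("gene")
        uni = set(sub.index) if universe is None else universe & set(sub.index)
        t_stats = sub.loc[list(uni), "t"]
        sig = set(sub.index[(sub["fdr"] < de_fdr)]) & uni
        p_ora, p_rank, names, dirs = [], [], [], []
        for name, members in gene_sets.items():
            mset = set(members) & uni
            if not mset or len(mset) == len(uni):
                logger.warning("set %s degenerate in universe; skipped", name)
                continue
            try:
                pr, direction = rank_test(t_stats, mset)
            except ValueError:
                continue
            if direction is None:
                logger.warning("set %s has undefined direction; dropped", name)
                continue
            names.append(name)
            p_ora.append(ora_test(sig, mset, uni))
            p_rank.append(pr)
            dirs.append(direction)
        if not names:
            continue
        pmat = pd.DataFrame({"ora": p_ora, "ranksum": p_rank}, index=names)
        combined = ensemble_combine(pmat)
        fdr = multipletests(combined["p_combined"], method="fdr_bh")[1]
        block = pd.DataFrame({
            "set": names,
            "contrast": contrast,
            "dataset_id": de["dataset_id"].iloc[0],
            "p_ora": p_ora,
            "p_ranksum": p_rank,
            "ensemble_rank": combined["ensemble_rank"].to_numpy(),
            "p_combined": combined["p_combined"].to_numpy(),
            "fdr": fdr,
            "direction": dirs,
        })
        rows.append(block)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["set", "contrast", "dataset_id", "p_ora", "p_ranksum",
                 "ensemble_rank", "p_combined", "fdr", "direction"])


def concordant_enriched_sets(
    tables: list[pd.DataFrame], fdr: float = 0.05
) -> dict[str, str]:
    """Sets significant with one direction in both contrasts of every dataset."""
    stacked = pd.concat(tables, ignore_index=True)
    n_cells = stacked[["dataset_id", "contrast"]].drop_duplicates().shape[0]
    out: dict[str, str] = {}
    for name, rows in stacked.groupby("set"):
        if len(rows) < n_cells:
            continue
        if (rows["fdr"] < fdr).all() and rows["direction"].nunique() == 1:
            out[str(name)] = rows["direction"].iloc[0]
    return out


def criterion2_genes(
    enriched: Mapping[str, str],
    gene_sets: GeneSetCollection,
    de_tables: list[pd.DataFrame],
) -> list[str]:
    """Member genes of enriched sets whose DE direction matches the set's.

    A gene's per-dataset direction is defined only when both contrasts
    agree; the gene must match the set direction in every dataset. A gene
    belonging to several enriched sets is reported once.
    """
    # per-dataset gene direction: defined iff both contrasts agree
    per_dataset: list[dict[str, str]] = []
    for table in de_tables:
        directions: dict[str, str] = {}
        for gene, rows in table.groupby("gene"):
            uniq = set(rows["direction"]) - {""}
            if len(uniq) == 1 and len(rows) == rows["contrast"].nunique():
                directions[str(gene)] = uniq.pop()
        per_dataset.append(directions)

    selected: set[str] = set()
    for set_name, set_dir in enriched.items():
        for gene in gene_sets[set_name]:
            if all(d.get(gene) == set_dir for d in per_dataset):
                selected.add(gene)
    return sorted(selected)
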