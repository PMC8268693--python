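"""Correlation of expression with copy number and methylation, and the
differential-regulation statistic.

For each candidate gene the Spearman correlation between expression and a
cis regulator (CNA copy ratio or DM beta value) is computed over all breast
cancers and within the TNBC and non-TNBC groups, classified by magnitude
(strong >= 0.450, moderate 0.300-0.449, weak 0.100-0.299, low/no < 0.100),
and compared between groups with

    deltaCor = | Cor(g, reg)_TNBC - Cor(g, reg)_non-TNBC |.

Because methylation silences transcription, a DM-regulated call also
requires a negative correlation; the sign-consistency flag records this.
Differential regulation across a set of genes (per pathway or overall) is
tested with the two-sided Mann-Whitney rank-sum on the per-gene
correlations, BH-adjusted across groupings.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

STRENGTH_BOUNDS = (0.450, 0.300, 0.100)  # strong / moderate / weak lower bounds
EXACT_MW_MAX_N = 12
GROUPS = ("all", "TNBC", "non-TNBC")


def classify_strength(rho: float, regulator: str = "CNA") -> tuple[str, bool]:
    """Magnitude class of a correlation plus the DM sign-consistency flag.

    The class is a function of |rho|; for DM the flag is True when rho < 0
    (methylation represses, so only negative correlations are
    sign-consistent with regulation). For CNA the flag is True when
    rho > 0.
    """
    if not np.isfinite(rho):
        raise ValueError("rho must be finite")
    a = abs(rho)
    if a >= STRENGTH_BOUNDS[0]:
        cls = "strong"
    elif a >= STRENGTH_BOUNDS[1]:
        cls = "moderate"
    elif a >= STRENGTH_BOUNDS[2]:
        cls = "weak"
    else:
        cls = "low/no"
    sign_ok = rho < 0 if regulator == "DM" else rho > 0
    return cls, bool(sign_ok)


def spearman_by_group(
    expr: ExpressionMatrix,
    layer: pd.DataFrame,
    samples: SampleTable,
    regulator: str,
    genes: list[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-gene Spearman correlation of expression with a regulator layer.

    Computed for 'all' (TNBC + non-TNBC), 'TNBC' and 'non-TNBC' groups with
    pairwise-complete observations; average ranks break ties. Genes with a
    constant vector or fewer than ``min_pairs`` complete pairs in a group
    are reported with missing rho (and a warning).
    """
    shared = [s for s in expr.samples if s in layer.columns]
    if not shared:
        raise ValueError("no shared samples between expression and regulator layer")
    group = samples.group_of()
    gene_list = genes if genes is not None else expr.genes
    gene_list = [g for g in gene_list if g in expr.values.index and g in layer.index]

    members = {
        "TNBC": [s for s in shared if group.get(s) == "TNBC"],
        "non-TNBC": [s for s in shared if group.get(s) == "non-TNBC"],
    }
    members["all"] = members["TNBC"] + members["non-TNBC"]

    rows = []
    for g in gene_list:
        for grp in GROUPS:
            ids = members[grp]
            x = expr.values.loc[g, ids].to_numpy(dtype=float)
            y = layer.loc[g, ids].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < min_pairs or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                logger.warning(
                    "gene %s group %s regulator %s: constant or too few pairs; "
                    "correlation reported missing", g, grp, regulator)
                rows.append((g, grp, regulator, np.nan, n, None, None))
                continue
            rho = float(stats.spearmanr(x[ok], y[ok]).statistic)
            cls, sign_ok = classify_strength(rho, regulator)
            rows.append((g, grp, regulator, rho, n, cls, sign_ok))
    return pd.DataFrame(
        rows, columns=["gene", "group", "regulator", "rho", "n", "strength", "sign_consistent"]
    )


def delta_cor(table: pd.DataFrame) -> pd.DataFrame:
    """Absolute TNBC vs non-TNBC correlation difference per gene/regulator.

    Entries missing either group correlation are skipped and logged.
    Symmetric under swapping the two groups; values lie in [0, 2].
    """
    rows = []
    pivot = table.pivot_table(index=["gene", "regulator"], columns="group",
                              values="rho", aggfunc="first")
    for (gene, regulator), r in pivot.iterrows():
        a, b = r.get("TNBC", np.nan), r.get("non-TNBC", np.nan)
        if np.isnan(a) or np.isnan(b):
            logger.warning("gene %s regulator %s: missing group correlation; "
                           "deltaCor omitted", gene, regulator)
            continue
        rows.append((gene, regulator, abs(a - b)))
    return pd.DataFrame(rows, columns=["gene", "regulator", "delta_cor"])


def test_differential_regulation(
    table: pd.DataFrame,
    pathway_genes: Mapping[str, list[str]] | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney test of per-gene correlations, TNBC vs non-TNBC.

    ``pathway_genes`` maps grouping name -> member genes; ``None`` tests all
    genes as one grouping. The exact null is used when the combined sample
    size is <= 12 (and no ties), otherwise the normal approximation with
    tie correction. ``paired=True`` switches to the Wilcoxon signed-rank
    test on per-gene correlation pairs. BH adjustment is applied across
    groupings within each regulator.
    """
    groupings = {"all_genes": sorted(set(table["gene"]))} if pathway_genes is None \
        else dict(pathway_genes)
    blocks = []
    for regulator, sub in table.groupby("regulator"):
        pivot = sub.pivot_table(index="gene", columns="group", values="rho",
                                aggfunc="first")
        rows = []
        for name, genes in groupings.items():
            present = [g for g in genes if g in pivot.index]
            pair = pivot.loc[present, ["TNBC", "non-TNBC"]].dropna()
            if len(pair) < 2:
                logger.warning("grouping %s (%s): <2 genes with both correlations; skipped",
                               name, regulator)
                continue
            a = pair["TNBC"].to_numpy()
            b = pair["non-TNBC"].to_numpy()
            if paired:
                if np.allclose(a, b):
                    stat, p = np.nan, 1.0
                else:
                    res = stats.wilcoxon(a, b, alternative="two-sided")
                    stat, p = float(res.statistic), float(res.pvalue)
            else:
                combined = np.concatenate([a, b])
                no_ties = len(np.unique(combined)) == len(combined)
                method = "exact" if (len(combined) <= EXACT_MW_MAX_N and no_ties) \
                    else "asymptotic"
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append((name, regulator, len(pair), stat, p))
        if rows:
            block = pd.DataFrame(rows, columns=["grouping", "regulator", "n_genes",
                                                "statistic", "p"])
            block["fdr"] = multipletests(block["p"], method="fdr_bh")[1]
            blocks.append(block)
    if not blocks:
        return pd.DataFrame(columns=["grouping", "regulator", "n_genes",
                                     "statistic", "p", "fdr"])
    return pd.concat(blocks, ignore_index=True)


def top_delta_cor(delta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k genes by deltaCor per regulator (the appendix-style report)."""
    return (delta.sort_values(["regulator", "delta_cor", "gene"],
                              ascending=[True, False, True], kind="mergesort")
            .groupby("regulator", group_keys=False).head(k).reset_index(drop=True))
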