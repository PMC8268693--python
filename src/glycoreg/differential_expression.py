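"""Criterion one: moderated differential expression and cross-dataset filtering.

Each dataset is tested for two contrasts (TNBC vs non-TNBC and TNBC vs
normal) with an empirical-Bayes moderated t-statistic: per-gene sample
variances are shrunk toward a pooled prior variance ``s0^2`` with prior
degrees of freedom ``d0``, both estimated by the method of moments on
``log s_g^2``. Genes significant (BH FDR below threshold) in both contrasts
with the same direction, in every dataset, form the common set; the top 50%
by mean |moderated t| become the criterion-1 list.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

CONTRASTS = (("TNBC", "non-TNBC"), ("TNBC", "normal"))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2``.

    Method of moments on ``z = log s_g^2`` using the scaled-F sampling
    distribution of sample variances: E[z] and Var[z] involve digamma /
    trigamma terms in ``d_g/2`` and ``d0/2``.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    dg = df[ok]
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    ebar = e.mean()
    n = len(e)
    evar = ((e - ebar) ** 2).sum() / (n - 1)
    target = evar - special.polygamma(1, dg / 2.0).mean()
    if target <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(ebar))
    else:
        d0 = 2.0 * _trigamma_inverse(float(target))
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_table(
    expr: ExpressionMatrix,
    samples: SampleTable,
    contrast: tuple[str, str],
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression for one two-group contrast.

    Parameters
    ----------
    contrast : (group_a, group_b)
        log2FC is mean(group_a) - mean(group_b); values are log2 already.
    prior_df : float, optional
        Override the estimated prior degrees of freedom. ``0`` disables
        shrinkage (ordinary pooled t); ``numpy.inf`` shrinks every gene's
        variance fully to the prior.

    Returns a DataFrame with one row per testable gene: log2fc, t, p, fdr,
    direction, n_a, n_b, contrast and dataset_id.
    """
    group = samples.group_of()
    a_ids = [s for s in expr.samples if group.get(s) == contrast[0]]
    b_ids = [s for s in expr.samples if group.get(s) == contrast[1]]
    if not a_ids or not b_ids:
        raise ValueError(f"contrast arm empty for contrast {contrast}")

    xa = expr.values[a_ids].to_numpy(dtype=float)
    xb = expr.values[b_ids].to_numpy(dtype=float)
    na = np.sum(~np.isnan(xa), axis=1)
    nb = np.sum(~np.isnan(xb), axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(np.where(np.isnan(xa), np.nan, xa), axis=1)
        mb = np.nanmean(np.where(np.isnan(xb), np.nan, xb), axis=1)
        va = np.nanvar(xa, axis=1, ddof=1)
        vb = np.nanvar(xb, axis=1, ddof=1)

    df_resid = na + nb - 2
    testable = (na >= 2) & (nb >= 2) & (df_resid > 0)
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.warning(
            "dataset %s contrast %s: excluding %d genes with zero residual df "
            "or <2 samples per arm", expr.dataset_id, contrast, n_dropped,
        )

    genes = np.asarray(expr.genes)[testable]
    na, nb = na[testable], nb[testable]
    ma, mb, va, vb = ma[testable], mb[testable], va[testable], vb[testable]
    dg = (na + nb - 2).astype(float)
    s2 = ((na - 1) * va + (nb - 1) * vb) / dg  # pooled variance

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, dg)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, dg)
    if d0 == 0:
        s2_tilde = s2
        df_total = dg
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.full_like(dg, np.inf)
    else:
        s2_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    log2fc = ma - mb
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    finite_df = np.where(np.isinf(df_total), 1e9, df_total)
    pval = 2.0 * stats.t.sf(np.abs(tval), finite_df)
    pval = np.clip(pval, 0.0, 1.0)
    fdr = multipletests(pval, method="fdr_bh")[1] if len(pval) else np.array([])

    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", ""))
    return pd.DataFrame(
        {
            "gene": genes,
            "contrast": f"{contrast[0]}_vs_{contrast[1]}",
            "log2fc": log2fc,
            "t": tval,
            "p": pval,
            "fdr": fdr,
            "direction": direction,
            "n_a": na,
            "n_b": nb,
            "dataset_id": expr.dataset_id,
        }
    )


def de_table(
    expr: ExpressionMatrix,
    samples: SampleTable,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Both standard contrasts stacked into one per-dataset DE table."""
    parts = [moderated_t_table(expr, samples, c, prior_df=prior_df) for c in CONTRASTS]
    return pd.concat(parts, ignore_index=True)


def concordant_de(de: pd.DataFrame, fdr_threshold: float = 0.05) -> dict[str, str]:
    """Genes significant in both contrasts with the same direction.

    Genes with an ambiguous direction (log2FC exactly 0) never qualify.
    """
    contrasts = de["contrast"].unique()
    if len(contrasts) < 2:
        raise ValueError("DE table must contain both contrasts")
    out: dict[str, str] = {}
    hits = de[(de["fdr"] < fdr_threshold) & (de["direction"] != "")]
    by_gene = hits.groupby("gene")
    for gene, rows in by_gene:
        if set(rows["contrast"]) >= set(contrasts) and rows["direction"].nunique() == 1:
            out[str(gene)] = rows["direction"].iloc[0]
    return out


def cross_dataset_intersection(
    per_dataset: list[dict[str, str]] | dict[str, dict[str, str]],
) -> dict[str, str]:
    """Genes concordantly differential in every dataset.

    Genes present in all datasets but with conflicting directions are
    dropped (and logged), mirroring the same-direction rule.
    """
    sets = list(per_dataset.values()) if isinstance(per_dataset, dict) else list(per_dataset)
    if len(sets) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    out: dict[str, str] = {}
    for gene in sorted(common):
        directions = {s[gene] for s in sets}
        if len(directions) == 1:
            out[gene] = directions.pop()
        else:
            logger.warning("gene %s dropped: direction conflict across datasets", gene)
    return out


def top_half(
    common_genes: dict[str, str] | set[str],
    de_tables: list[pd.DataFrame],
) -> list[str]:
    """Top 50% (ceil) of the common genes by mean |moderated t|.

    Ties are broken by smaller mean FDR, then lexicographic gene symbol.
    """
    genes = sorted(common_genes)
    if not genes:
        raise ValueError("top_half requires a non-empty gene list")
    stacked = pd.concat(de_tables, ignore_index=True)
    stacked = stacked[stacked["gene"].isin(genes)]
    score = stacked.groupby("gene")["t"].apply(lambda t: np.mean(np.abs(t)))
    mean_fdr = stacked.groupby("gene")["fdr"].mean()
    ranking = (
        pd.DataFrame({"score": score, "mean_fdr": mean_fdr})
        .reindex(genes)
        .reset_index(names="gene")
        .sort_values(by=["score", "mean_fdr", "gene"],
                     ascending=[False, True, True], kind="mergesort")
    )
    k = math.ceil(len(genes) / 2)
    return ranking["gene"].head(k).tolist()
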