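"""TF-glycogene regulatory network inference by stability selection.

ChIP peaks within +/-2 kb of a gene's TSS define the candidate TFs for
that gene. Within each sample group, every candidate gene is modelled by
an L1-penalized regression of its expression on the expression of its
bound TFs, with the gene's own CNA and DM values entering as unpenalized
covariates (so TF selection is conditional on cis effects). Because lasso
selection is unstable, the fit is repeated (default 100 times) on random
80% subsamples and TFs are retained by selection frequency, with the
frequency threshold chosen to maximize held-out predictive R^2 of an OLS
refit. The retained edges form one bipartite TF-gene network per group;
subtracting the non-TNBC network from the TNBC network yields the
TNBC-specific differential network, whose highly connected TFs (>= 4
targets) are reported as master regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold

from .io_formats import BipartiteNetwork, GenomicIntervalSet, TSSTable

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2000
THRESHOLD_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


# ---------------------------------------------------------------------------
# ChIP-evidence binding map
# ---------------------------------------------------------------------------


def annotate_binding(
    peaks: GenomicIntervalSet, tss: TSSTable, window: int = DEFAULT_WINDOW
) -> dict[str, set[str]]:
    """TF -> candidate target genes with a peak in the promoter window.

    A (tf, gene) pair is included iff some peak interval overlaps the
    half-open window [tss - window, tss + window) by at least 1 bp. The
    window is symmetric around the TSS regardless of strand.
    """
    out: dict[str, set[str]] = {}
    p = peaks.table
    for _, gene_row in tss.table.iterrows():
        lo = gene_row["tss"] - window
        hi = gene_row["tss"] + window
        hit = p[(p["chrom"] == gene_row["chrom"]) & (p["start"] < hi) & (p["end"] > lo)]
        for tf in hit["tf"].unique():
            out.setdefault(str(tf), set()).add(str(gene_row["gene"]))
    return out


def bound_tfs_of(binding: dict[str, set[str]], gene: str) -> list[str]:
    return sorted(tf for tf, targets in binding.items() if gene in targets)


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


class StabilityLassoSelector(BaseEstimator):
    """Repeated-subsample lasso feature selection with optional unpenalized
    covariates.

    Parameters
    ----------
    n_rep : int
        Number of subsample repetitions (the workflow's default is 100).
    subsample : float
        Fraction of samples drawn without replacement per repetition.
    penalize_covariates : bool
        If False (default), covariates are kept unpenalized by projecting
        the response and the penalized predictors onto the orthogonal
        complement of the covariate span before the lasso fit
        (Frisch-Waugh); if True they are appended as ordinary penalized
        columns.
    random_state : int
        Seed controlling subsampling and the internal lasso CV folds.

    Attributes
    ----------
    frequencies_ : pandas.Series
        Per-feature selection frequency in [0, 1] over repetitions.
    feature_names_ : list of str
    """

    def __init__(
        self,
        n_rep: int = 100,
        subsample: float = 0.8,
        cv: int = 3,
        n_alphas: int = 10,
        penalize_covariates: bool = False,
        random_state: int = 0,
    ):
        self.n_rep = n_rep
        self.subsample = subsample
        self.cv = cv
        self.n_alphas = n_alphas
        self.penalize_covariates = penalize_covariates
        self.random_state = random_state

    @staticmethod
    def _residualize(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
        """Residuals of Z columns after OLS on [1, C]."""
        design = np.column_stack([np.ones(len(C)), C])
        coef, *_ = np.linalg.lstsq(design, Z, rcond=None)
        return Z - design @ coef

    def fit(self, X, y, covariates=None):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else \
            [f"x{j}" for j in range(np.asarray(X).shape[1])]
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=float)
        n, p = Xa.shape
        if n < 10:
            raise ValueError("stability selection needs at least 10 samples")
        C = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
        if C is not None and C.shape[0] != n:
            C = C.T
        if C is not None and self.penalize_covariates:
            Xa = np.column_stack([Xa, C])
            names = names + [f"cov{j}" for j in range(C.shape[1])]
            C = None
            p = Xa.shape[1]

        rng = np.random.default_rng(self.random_state)
        k = max(int(round(self.subsample * n)), self.cv + 2)
        hits = np.zeros(p)
        for _ in range(self.n_rep):
            idx = rng.choice(n, size=k, replace=False)
            Xs, ys = Xa[idx], ya[idx]
            Cs = None if C is None else C[idx]
            if Cs is not None:
                Zs = self._residualize(np.column_stack([Xs, ys[:, None]]), Cs)
                Xs, ys = Zs[:, :p], Zs[:, p]
            mu, sd = Xs.mean(axis=0), Xs.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xs = (Xs - mu) / sd
            seed = int(rng.integers(2 ** 31 - 1))
            yc = ys - ys.mean()
            path = LassoCV(
                cv=KFold(self.cv, shuffle=True, random_state=seed),
                alphas=self.n_alphas, max_iter=5000, tol=1e-4,
            ).fit(Xs, yc)
            # 1-SE rule on the CV curve: largest alpha within one standard
            # error of the minimum mean CV error (sparser, stabler choice)
            mean_mse = path.mse_path_.mean(axis=1)
            se = path.mse_path_.std(axis=1, ddof=1) / np.sqrt(path.mse_path_.shape[1])
            i_min = int(np.argmin(mean_mse))
            ok = mean_mse <= mean_mse[i_min] + se[i_min]
            alpha_1se = float(path.alphas_[ok].max())
            model = Lasso(alpha=alpha_1se, max_iter=5000, tol=1e-4).fit(Xs, yc)
            hits += (model.coef_ != 0.0).astype(float)
        self.feature_names_ = names
        self.frequencies_ = pd.Series(hits / self.n_rep, index=names)
        return self

    def get_support(self, threshold: float = 0.5) -> list[str]:
        return sorted(self.frequencies_.index[self.frequencies_ >= threshold])


@dataclass
class StabilityProfile:
    """Per-gene TF selection frequencies and the chosen threshold."""

    gene: str
    frequencies: pd.Series  # TF -> selection frequency
    threshold: float | None = None
    retained: list[str] = field(default_factory=list)


def stability_select(
    gene: str,
    expr_row: pd.Series,
    tf_expr: pd.DataFrame,
    cna_row: pd.Series | None,
    dm_row: pd.Series | None,
    group_samples: list[str],
    binding: dict[str, set[str]] | None = None,
    n_rep: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    penalize_covariates: bool = False,
) -> StabilityProfile:
    """Stability-selection frequencies of a gene's bound TFs in one group.

    Predictors are the expression of TFs with ChIP evidence for this gene
    (all TFs when ``binding`` is None); the gene's CNA and DM values enter
    as unpenalized covariates. Returns an empty profile (logged) when no TF
    is bound.
    """
    tfs = bound_tfs_of(binding, gene) if binding is not None else sorted(tf_expr.index)
    tfs = [t for t in tfs if t in tf_expr.index]
    if not tfs:
        logger.warning("gene %s has no bound TFs; empty stability profile", gene)
        return StabilityProfile(gene=gene, frequencies=pd.Series(dtype=float))
    X = tf_expr.loc[tfs, group_samples].T
    y = expr_row[group_samples].to_numpy(dtype=float)
    cov_cols = []
    if cna_row is not None:
        cov_cols.append(cna_row[group_samples].to_numpy(dtype=float))
    if dm_row is not None:
        cov_cols.append(dm_row[group_samples].to_numpy(dtype=float))
    C = np.column_stack(cov_cols) if cov_cols else None
    selector = StabilityLassoSelector(
        n_rep=n_rep, subsample=subsample, random_state=seed,
        penalize_covariates=penalize_covariates,
    ).fit(X, y, covariates=C)
    freqs = selector.frequencies_[selector.frequencies_.index.isin(tfs)]
    return StabilityProfile(gene=gene, frequencies=freqs)


def choose_threshold(
    profile: StabilityProfile,
    tf_expr: pd.DataFrame,
    expr_row: pd.Series,
    group_samples: list[str],
    grid: tuple[float, ...] = THRESHOLD_GRID,
    cv: int = 5,
    seed: int = 0,
) -> StabilityProfile:
    """Pick the frequency threshold maximizing held-out R^2 of an OLS refit.

    Thresholds are scanned from sparsest (largest) down; exact ties in CV
    R^2 (identical retained sets) keep the larger threshold. Returns the
    profile with ``threshold`` and ``retained`` filled; a profile whose
    every threshold retains no TF keeps ``threshold=None`` (the gene is
    excluded from networks).
    """
    if profile.frequencies.empty:
        return profile
    y = expr_row[group_samples].to_numpy(dtype=float)
    best_r2, best_thr, best_set = -np.inf, None, []
    seen: dict[tuple[str, ...], float] = {}
    for thr in sorted(grid, reverse=True):
        retained = sorted(profile.frequencies.index[profile.frequencies >= thr])
        if not retained:
            continue
        key = tuple(retained)
        if key in seen:
            r2 = seen[key]
        else:
            X = tf_expr.loc[retained, group_samples].T.to_numpy(dtype=float)
            folds = KFold(cv, shuffle=True, random_state=seed)
            scores = []
            for tr, te in folds.split(X):
                fit = LinearRegression().fit(X[tr], y[tr])
                pred = fit.predict(X[te])
                ss_res = float(((y[te] - pred) ** 2).sum())
                ss_tot = float(((y[te] - y[te].mean()) ** 2).sum())
                scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
            r2 = float(np.mean(scores))
            seen[key] = r2
        if r2 > best_r2:
            best_r2, best_thr, best_set = r2, thr, retained
    if best_thr is not None and best_r2 <= 0.0:
        # no threshold beats the intercept-only model out of sample: the
        # gene has no predictive TF set in this group
        logger.info("gene %s: best CV R^2 %.3f <= 0; no TFs retained",
                    profile.gene, best_r2)
        best_thr, best_set = None, []
    profile.threshold = best_thr
    profile.retained = best_set
    return profile


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def build_group_network(profiles: list[StabilityProfile], group: str) -> BipartiteNetwork:
    """Bipartite TF-gene network from thresholded stability profiles."""
    rows = []
    for p in profiles:
        if p.threshold is None:
            continue
        for tf in p.retained:
            rows.append((tf, p.gene, float(p.frequencies[tf])))
    edges = pd.DataFrame(rows, columns=["tf", "gene", "frequency"])
    return BipartiteNetwork(edges=edges, group_label=group)


def network_from_target_lists(
    targets: dict[str, list[str]], group: str = "TNBC"
) -> BipartiteNetwork:
    """Build a network from explicit TF -> target lists (frequency 1.0)."""
    rows = [(tf, g, 1.0) for tf, genes in targets.items() for g in genes]
    return BipartiteNetwork(pd.DataFrame(rows, columns=["tf", "gene", "frequency"]),
                            group_label=group)


@dataclass
class DifferentialNetworkReport:
    """TNBC-specific edges and per-TF target counts."""

    edges: pd.DataFrame  # columns tf, gene, frequency (TNBC frequencies)
    tf_target_counts: pd.Series  # tf -> number of TNBC-specific targets

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["gene"]))


def differential_network(
    tnbc: BipartiteNetwork, non_tnbc: BipartiteNetwork
) -> DifferentialNetworkReport:
    """Subtract the non-TNBC network: keep TNBC edges absent from non-TNBC.

    Pure (tf, gene) set subtraction; selection frequencies are carried from
    the TNBC network for reporting only.
    """
    drop = non_tnbc.edge_set()
    keep = [not ((tf, g) in drop)
            for tf, g in zip(tnbc.edges["tf"], tnbc.edges["gene"])]
    edges = tnbc.edges[keep].reset_index(drop=True)
    counts = edges.groupby("tf")["gene"].nunique().sort_values(ascending=False)
    return DifferentialNetworkReport(edges=edges, tf_target_counts=counts)


def master_regulators(
    report: DifferentialNetworkReport, min_targets: int = 4
) -> pd.DataFrame:
    """TFs with >= ``min_targets`` differential targets, ranked by count
    (descending) then name."""
    counts = report.tf_target_counts
    keep = counts[counts >= min_targets]
    out = pd.DataFrame({"tf": keep.index, "n_targets": keep.to_numpy()})
    return out.sort_values(["n_targets", "tf"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def infer_group_network(
    genes: list[str],
    expr: pd.DataFrame,
    tf_expr: pd.DataFrame,
    cna: pd.DataFrame | None,
    dm: pd.DataFrame | None,
    group_samples: list[str],
    group: str,
    binding: dict[str, set[str]],
    n_rep: int = 100,
    seed: int = 0,
) -> tuple[BipartiteNetwork, list[StabilityProfile]]:
    """Run stability selection + threshold choice for every gene in a group."""
    profiles = []
    for i, gene in enumerate(genes):
        profile = stability_select(
            gene,
            expr.loc[gene],
            tf_expr,
            None if cna is None else cna.loc[gene],
            None if dm is None else dm.loc[gene],
            group_samples,
            binding=binding,
            n_rep=n_rep,
            seed=seed + i,
        )
        profile = choose_threshold(profile, tf_expr, expr.loc[gene],
                                   group_samples, seed=seed + i)
        profiles.append(profile)
    return build_group_network(profiles, group), profiles
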