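"""Criterion three: graph-regularized sparse logistic models of TNBC status.

A gene co-membership graph is built from the enriched gene sets (nodes are
genes, an edge joins two genes sharing at least one set). Classification
uses an L1-penalized logistic regression with an additional quadratic
penalty on the degree-normalized graph Laplacian,

    (1/n) sum_i log(1 + exp(-y_i (b0 + x_i beta)))
        + lambda1 ||beta||_1 + lambda2 beta' L beta,

which encourages connected genes to receive similar coefficients
("selecting genes that are biologically related"). The objective is solved
with FISTA (proximal gradient with Nesterov acceleration); lambda2 = 0
recovers plain L1-penalized logistic regression. Gene stability is
summarised over repeated stratified train/test resamples, and genes
selected at least once in at least two datasets pass the criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class CoMembershipGraph:
    """Gene graph from shared gene-set membership."""

    nodes: list[str]
    graph: nx.Graph

    @classmethod
    def from_gene_sets(cls, sets: GeneSetCollection) -> "CoMembershipGraph":
        g = nx.Graph()
        for _, members in sets.items():
            uniq = sorted(set(members))
            g.add_nodes_from(uniq)
            for i, a in enumerate(uniq):
                for b in uniq[i + 1:]:
                    g.add_edge(a, b)
        return cls(nodes=sorted(g.nodes), graph=g)

    def laplacian(self, nodes: list[str] | None = None, normalized: bool = True) -> np.ndarray:
        """(Degree-normalized) Laplacian aligned to ``nodes`` order.

        Genes absent from the graph contribute zero rows/columns, so the
        penalty is inert for them.
        """
        nodes = nodes if nodes is not None else self.nodes
        n = len(nodes)
        adj = np.zeros((n, n))
        idx = {g: i for i, g in enumerate(nodes)}
        for a, b in self.graph.edges:
            if a in idx and b in idx:
                adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1.0
        deg = adj.sum(axis=1)
        if not normalized:
            return np.diag(deg) - adj
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
        lap = -adj * dinv[:, None] * dinv[None, :]
        lap[np.arange(n), np.arange(n)] = (deg > 0).astype(float)
        return lap


def build_graph(enriched_sets: GeneSetCollection) -> CoMembershipGraph:
    """Edge (a, b) iff a != b co-occur in at least one enriched set."""
    if len(enriched_sets) == 0:
        raise ValueError("empty gene-set collection")
    return CoMembershipGraph.from_gene_sets(enriched_sets)


class GraphLogisticClassifier(BaseEstimator, ClassifierMixin):
    """Sparse logistic regression with a graph-Laplacian smoothness penalty.

    Parameters
    ----------
    lambda1 : float
        L1 penalty weight (per-sample-scaled logistic loss).
    lambda2 : float
        Weight on ``beta' L beta``; 0 gives plain L1 logistic regression.
    laplacian : ndarray of shape (n_features, n_features), optional
        Positive-semidefinite graph Laplacian aligned with the columns of
        X. ``None`` is treated as the zero matrix.
    standardize : bool
        Center/scale columns before fitting (coefficients are reported on
        the standardized scale).

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    n_iter_ : int
    classes_ : ndarray of the two class labels (positive class is
        ``classes_[1]``).
    """

    def __init__(
        self,
        lambda1: float = 0.01,
        lambda2: float = 0.0,
        laplacian: np.ndarray | None = None,
        standardize: bool = True,
        max_iter: int = 5000,
        tol: float = 1e-8,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.laplacian = laplacian
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol

    def _objective(self, X, y01, beta, b0):
        z = b0 + X @ beta
        # log(1 + exp(-s*z)) written stably via logaddexp
        loss = np.mean(np.logaddexp(0.0, z) - y01 * z)
        pen = self.lambda1 * np.abs(beta).sum()
        if self.laplacian is not None and self.lambda2 > 0:
            pen += self.lambda2 * float(beta @ self.laplacian @ beta)
        return loss + pen

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"GraphLogisticClassifier requires exactly 2 classes, got {list(self.classes_)}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        n, p = X.shape

        if self.standardize:
            self._mean = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self._scale = np.where(sd > 0, sd, 1.0)
        else:
            self._mean = np.zeros(p)
            self._scale = np.ones(p)
        Xs = (X - self._mean) / self._scale

        lap = self.laplacian if (self.laplacian is not None and self.lambda2 > 0) else None
        # Lipschitz bound for the smooth part: sigma_max(X)^2 / (4n) for the
        # logistic loss plus 2*lambda2*lambda_max(L).
        sigma = np.linalg.norm(Xs, 2)
        lip = sigma ** 2 / (4.0 * n) + 0.25  # +0.25 covers the intercept coordinate
        if lap is not None:
            lip += 2.0 * self.lambda2 * float(np.linalg.eigvalsh(lap)[-1])
        step = 1.0 / max(lip, 1e-12)

        beta = np.zeros(p)
        b0 = 0.0
        zeta, zeta0 = beta.copy(), b0  # FISTA extrapolation point
        t_acc = 1.0
        obj_prev = self._objective(Xs, y01, beta, b0)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            z = zeta0 + Xs @ zeta
            prob = 1.0 / (1.0 + np.exp(-z))
            resid = prob - y01
            grad = Xs.T @ resid / n
            grad0 = resid.mean()
            if lap is not None:
                grad = grad + 2.0 * self.lambda2 * (lap @ zeta)
            beta_new = zeta - step * grad
            beta_new = np.sign(beta_new) * np.maximum(np.abs(beta_new) - step * self.lambda1, 0.0)
            b0_new = zeta0 - step * grad0

            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_acc ** 2)) / 2.0
            zeta = beta_new + (t_acc - 1.0) / t_new * (beta_new - beta)
            zeta0 = b0_new + (t_acc - 1.0) / t_new * (b0_new - b0)
            beta, b0, t_acc = beta_new, b0_new, t_new

            if n_iter % 10 == 0:
                obj = self._objective(Xs, y01, beta, b0)
                if obj > obj_prev:  # FISTA restart on non-monotone step
                    zeta, zeta0, t_acc = beta.copy(), b0, 1.0
                if abs(obj_prev - obj) < self.tol * max(1.0, abs(obj_prev)):
                    obj_prev = obj
                    break
                obj_prev = obj

        self.coef_ = beta
        self.intercept_ = float(b0)
        self.n_iter_ = n_iter
        self.objective_ = float(self._objective(Xs, y01, beta, b0))
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        Xs = (np.asarray(X, dtype=float) - self._mean) / self._scale
        return self.intercept_ + Xs @ self.coef_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0.0,
                        self.classes_[1], self.classes_[0])

    def selected_features(self) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.flatnonzero(self.coef_ != 0.0)


def fit_graph_logistic(
    X: np.ndarray,
    y: np.ndarray,
    laplacian: np.ndarray | None,
    lambda1: float,
    lambda2: float,
    **kwargs,
) -> np.ndarray:
    """Convenience wrapper returning the fitted coefficient vector."""
    model = GraphLogisticClassifier(
        lambda1=lambda1, lambda2=lambda2, laplacian=laplacian, **kwargs
    )
    return model.fit(X, y).coef_


@dataclass
class SelectionSummary:
    """Gene selection counts and held-out metrics over repeated models."""

    dataset_id: str
    n_models: int
    counts: pd.Series  # gene -> times selected (0..n_models)
    model_metrics: pd.DataFrame  # model, sensitivity, specificity, lambda1, lambda2

    def selected_genes(self, min_times: int = 1) -> set[str]:
        return set(self.counts.index[self.counts >= min_times])


def _lambda1_path(Xs: np.ndarray, y01: np.ndarray, n_values: int = 6) -> np.ndarray:
    """Log-spaced path below the smallest lambda1 zeroing all coefficients."""
    n = len(y01)
    lam_max = np.abs(Xs.T @ (y01 - y01.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 2e-2, n_values)


def _cv_choose(
    X: np.ndarray,
    y: np.ndarray,
    laplacian: np.ndarray | None,
    lambda2_grid: tuple[float, ...],
    seed: int,
    n_folds: int = 3,
) -> tuple[float, float]:
    """Pick (lambda1, lambda2) by stratified CV with the 1-SE rule.

    Accuracy is averaged over folds; among (lambda1, lambda2) pairs whose
    mean CV accuracy is within one standard error of the best, the sparsest
    (largest lambda1, then smallest lambda2) wins.
    """
    y01 = (y == np.unique(y)[1]).astype(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    Xs = (X - mu) / np.where(sd > 0, sd, 1.0)
    path = _lambda1_path(Xs, y01)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    records = []
    for lam2 in lambda2_grid:
        for lam1 in path:
            accs = []
            for tr, te in cv.split(X, y):
                model = GraphLogisticClassifier(
                    lambda1=lam1, lambda2=lam2, laplacian=laplacian,
                    max_iter=800, tol=1e-6,
                ).fit(X[tr], y[tr])
                accs.append(float(np.mean(model.predict(X[te]) == y[te])))
            records.append((lam1, lam2, float(np.mean(accs)),
                            float(np.std(accs, ddof=1) / np.sqrt(len(accs)))))
    table = pd.DataFrame(records, columns=["lambda1", "lambda2", "acc", "se"])
    best = table.loc[table["acc"].idxmax()]
    ok = table[table["acc"] >= best["acc"] - best["se"]]
    ok = ok.sort_values(["lambda1", "lambda2"], ascending=[False, True])
    return float(ok.iloc[0]["lambda1"]), float(ok.iloc[0]["lambda2"])


def repeated_models(
    X: pd.DataFrame,
    y: pd.Series,
    graph: CoMembershipGraph,
    dataset_id: str,
    n_models: int = 10,
    seed: int = 0,
    lambda2_grid: tuple[float, ...] = (0.0, 1.0),
    positive_class: str = "TNBC",
) -> SelectionSummary:
    """Fit ``n_models`` stratified 80/20 resampled models and summarise.

    ``X``: samples x genes expression; ``y``: group labels (two classes).
    Each model tunes (lambda1, lambda2) by internal CV (1-SE rule), refits
    on the 80% training split, and reports sensitivity/specificity on the
    held-out 20% at probability threshold 0.5. A gene counts as selected in
    a model when its coefficient is nonzero.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two groups, got {list(classes)}")
    if counts.min() < 5:
        raise ValueError("each group needs at least 5 samples")
    genes = list(X.columns)
    lap = graph.laplacian(nodes=genes)
    Xa = X.to_numpy(dtype=float)
    # order classes so the positive class is classes_[1]
    ya = pd.Categorical(y, categories=[c for c in classes if c != positive_class]
                        + [positive_class]).codes
    ya = np.asarray(ya)

    splitter = StratifiedShuffleSplit(n_splits=n_models, test_size=0.2, random_state=seed)
    sel_counts = pd.Series(0, index=genes, dtype=int)
    metrics = []
    for m, (tr, te) in enumerate(splitter.split(Xa, ya)):
        lam1, lam2 = _cv_choose(Xa[tr], ya[tr], lap, lambda2_grid, seed=seed + m)
        model = GraphLogisticClassifier(
            lambda1=lam1, lambda2=lam2, laplacian=lap, max_iter=5000, tol=1e-9,
        ).fit(Xa[tr], ya[tr])
        if len(model.selected_features()) == 0:
            # intercept-only model: no informative predictions to score
            logger.warning("dataset %s model %d selected no genes; "
                           "held-out metrics undefined", dataset_id, m)
            sens = spec = np.nan
        else:
            pred = (model.predict_proba(Xa[te])[:, 1] >= 0.5).astype(int)
            truth = ya[te]
            tp = int(((pred == 1) & (truth == 1)).sum())
            tn = int(((pred == 0) & (truth == 0)).sum())
            fn = int(((pred == 0) & (truth == 1)).sum())
            fp = int(((pred == 1) & (truth == 0)).sum())
            sens = tp / (tp + fn) if tp + fn else np.nan
            spec = tn / (tn + fp) if tn + fp else np.nan
        for j in model.selected_features():
            sel_counts.iloc[j] += 1
        metrics.append((m, sens, spec, lam1, lam2))
    return SelectionSummary(
        dataset_id=dataset_id,
        n_models=n_models,
        counts=sel_counts,
        model_metrics=pd.DataFrame(
            metrics, columns=["model", "sensitivity", "specificity", "lambda1", "lambda2"]
        ),
    )


def predictive_gene_rule(
    summaries: list[SelectionSummary], min_datasets: int = 2
) -> list[str]:
    """Genes selected at least once in at least ``min_datasets`` datasets."""
    if len(summaries) < 2:
        raise ValueError("need summaries from at least 2 datasets")
    tally: dict[str, int] = {}
    for s in summaries:
        for g in s.selected_genes(min_times=1):
            tally[g] = tally.get(g, 0) + 1
    return sorted(g for g, k in tally.items() if k >= min_datasets)
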