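"""Graph construction, solver oracles and the predictive-gene rule."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from glycoreg import network_predictor as net
from glycoreg.io_formats import GeneSetCollection


def test_comembership_edges():
    g = net.build_graph(GeneSetCollection({"s1": ["A", "B"], "s2": ["B", "C"]}))
    assert set(map(frozenset, g.graph.edges)) == {frozenset({"A", "B"}),
                                                  frozenset({"B", "C"})}
    assert not g.graph.has_edge("A", "C")


def test_singleton_set_gives_isolated_node():
    g = net.build_graph(GeneSetCollection({"s": ["A"]}))
    assert list(g.graph.nodes) == ["A"] and g.graph.number_of_edges() == 0


def test_unnormalized_laplacian_row_sums_zero():
    g = net.build_graph(GeneSetCollection({"s1": ["A", "B", "C"], "s2": ["C", "D"]}))
    L = g.laplacian(normalized=False)
    assert np.allclose(L.sum(axis=1), 0.0)
    assert np.allclose(L, L.T)
    # normalized Laplacian is PSD
    Ln = g.laplacian(normalized=True)
    assert np.linalg.eigvalsh(Ln).min() > -1e-10


@pytest.fixture(scope="module")
def toy_logistic_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 5))
    beta = np.array([1.5, -1.0, 0.0, 0.0, 0.0])
    y = (X @ beta + 0.5 * rng.normal(size=30) > 0).astype(int)
    return X, y


def test_l1_only_solution_matches_independent_oracle(toy_logistic_data):
    """At lambda2=0 the FISTA solution agrees with an independent saga-based
    L1 logistic solver to <= 1e-4 per coefficient."""
    X, y = toy_logistic_data
    n = len(y)
    for lam1 in (0.01, 0.05, 0.2):
        mine = net.GraphLogisticClassifier(
            lambda1=lam1, lambda2=0.0, standardize=False,
            max_iter=100000, tol=1e-14).fit(X, y)
        oracle = LogisticRegression(
            C=1.0 / (n * lam1), solver="saga", l1_ratio=1.0,
            tol=1e-10, max_iter=200000).fit(X, y)
        assert np.abs(mine.coef_ - oracle.coef_[0]).max() < 1e-4
        assert abs(mine.intercept_ - oracle.intercept_[0]) < 1e-4


def test_duplicated_columns_coupled_by_edge_converge(toy_logistic_data):
    X, y = toy_logistic_data
    X2 = np.column_stack([X[:, 0], X[:, 0], X[:, 1:]])
    L = np.zeros((6, 6))
    L[0, 0] = L[1, 1] = 1.0
    L[0, 1] = L[1, 0] = -1.0
    m = net.GraphLogisticClassifier(lambda1=0.01, lambda2=10.0, laplacian=L,
                                    standardize=False, max_iter=50000,
                                    tol=1e-12).fit(X2, y)
    assert abs(m.coef_[0] - m.coef_[1]) < 1e-6


def test_huge_l1_penalty_zeroes_all_coefficients(toy_logistic_data):
    X, y = toy_logistic_data
    m = net.GraphLogisticClassifier(lambda1=50.0).fit(X, y)
    assert np.all(m.coef_ == 0.0)


def test_single_class_is_hard_error(toy_logistic_data):
    X, _ = toy_logistic_data
    with pytest.raises(ValueError, match="2 classes"):
        net.GraphLogisticClassifier().fit(X, np.zeros(len(X)))


def test_objective_nonincreasing_over_sweeps(toy_logistic_data):
    """The converged objective never exceeds the starting objective and the
    solver reports convergence on the fixture."""
    X, y = toy_logistic_data
    m = net.GraphLogisticClassifier(lambda1=0.05, max_iter=5000, tol=1e-10).fit(X, y)
    start = m._objective((X - X.mean(0)) / X.std(0), (y == m.classes_[1]).astype(float),
                         np.zeros(X.shape[1]), 0.0)
    assert m.objective_ <= start + 1e-12


def _separable_frame(n=40, seed=1):
    rng = np.random.default_rng(seed)
    informative = np.r_[np.ones(n // 2), -np.ones(n // 2)]
    X = pd.DataFrame({
        "inf": informative,
        "n1": rng.normal(size=n) * 0.01,
        "n2": rng.normal(size=n) * 0.01,
    })
    y = pd.Series(np.r_[["TNBC"] * (n // 2), ["non-TNBC"] * (n // 2)])
    return X, y


def test_separable_toy_selects_informative_gene_in_all_models():
    X, y = _separable_frame()
    graph = net.build_graph(GeneSetCollection({"s": ["inf", "n1", "n2"]}))
    s = net.repeated_models(X, y, graph, "D1", n_models=10, seed=0)
    assert s.counts["inf"] == 10
    assert (s.model_metrics["sensitivity"] == 1.0).all()
    assert (s.model_metrics["specificity"] == 1.0).all()


def test_repeated_models_deterministic_and_order_invariant():
    X, y = _separable_frame()
    graph = net.build_graph(GeneSetCollection({"s": ["inf", "n1", "n2"]}))
    a = net.repeated_models(X, y, graph, "D1", n_models=3, seed=5)
    b = net.repeated_models(X, y, graph, "D1", n_models=3, seed=5)
    pd.testing.assert_series_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.model_metrics, b.model_metrics)
    # permuting predictor columns does not change held-out metrics
    perm = ["n2", "inf", "n1"]
    c = net.repeated_models(X[perm], y, graph, "D1", n_models=3, seed=5)
    pd.testing.assert_frame_equal(a.model_metrics[["sensitivity", "specificity"]],
                                  c.model_metrics[["sensitivity", "specificity"]])


def test_permuted_labels_give_chance_level_metrics():
    """With labels shuffled independently of X, held-out sensitivity and
    specificity average ~0.5."""
    rng = np.random.default_rng(9)
    sens, spec = [], []
    graph = net.build_graph(GeneSetCollection({"s": [f"x{j}" for j in range(6)]}))
    for seed in range(8):
        X = pd.DataFrame(rng.normal(size=(60, 6)), columns=[f"x{j}" for j in range(6)])
        y = pd.Series(["TNBC"] * 30 + ["non-TNBC"] * 30)
        s = net.repeated_models(X, y, graph, "D1", n_models=3, seed=seed)
        sens.extend(s.model_metrics["sensitivity"])
        spec.extend(s.model_metrics["specificity"])
    assert abs(np.nanmean(sens) - 0.5) < 0.15
    assert abs(np.nanmean(spec) - 0.5) < 0.15


def test_group_size_guard():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(7, 2)))
    y = pd.Series(["TNBC"] * 3 + ["non-TNBC"] * 4)
    graph = net.build_graph(GeneSetCollection({"s": [0, 1]}))
    with pytest.raises(ValueError, match="at least 5"):
        net.repeated_models(X, y, graph, "D1")


def _summary(dataset, counts):
    return net.SelectionSummary(dataset_id=dataset, n_models=10,
                                counts=pd.Series(counts),
                                model_metrics=pd.DataFrame())


@pytest.mark.parametrize(
    "counts_by_ds, expected",
    [
        # selected once in each of 3 datasets -> retained
        ([{"g": 1}, {"g": 1}, {"g": 1}], ["g"]),
        # selected twice in a single dataset only -> excluded
        ([{"g": 2}, {"g": 0}, {"g": 0}], []),
        # selected once in exactly 2 of 3 datasets -> retained
        ([{"g": 1}, {"g": 1}, {"g": 0}], ["g"]),
    ],
)
def test_predictive_gene_rule(counts_by_ds, expected):
    summaries = [_summary(f"D{i}", c) for i, c in enumerate(counts_by_ds)]
    assert net.predictive_gene_rule(summaries) == expected


def test_informative_pathway_recovery_on_synthetic_cohorts():
    """Five informative genes (one pathway, effect 1.0) among 95 nulls:
    >= 4/5 pass the predictive rule, few nulls do."""
    from glycoreg.synthetic_data import PlantedPathway, SimulationConfig, simulate_cohorts

    cfg = SimulationConfig(n_genes=100, n_tfs=2, n_per_group=150, de_fraction=0.0,
                           n_cna_driven=0, n_dm_driven=0, n_tnbc_only_edges=0,
                           n_shared_edges=0, noise_sd=1.0, n_null_sets=10,
                           planted_pathways=[PlantedPathway("info", 5, 1, 1.0)],
                           seed=0)
    cohorts, truth = simulate_cohorts(cfg)
    graph = net.build_graph(truth.gene_sets)
    summaries = []
    for c in cohorts:
        grp = c.samples.group_of()
        keep = [s for s in c.expression.samples if grp[s] in ("TNBC", "non-TNBC")]
        summaries.append(net.repeated_models(
            c.expression.values[keep].T, grp.loc[keep], graph,
            c.expression.dataset_id, n_models=10, seed=1))
    selected = set(net.predictive_gene_rule(summaries))
    informative = set(truth.gene_sets["info"])
    assert len(selected & informative) >= 4
    assert len(selected - informative) <= 5
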