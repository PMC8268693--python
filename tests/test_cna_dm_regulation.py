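"""Correlation arithmetic, strength classes and differential-regulation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycoreg import cna_dm_regulation as reg
from tests.conftest import make_expression, make_samples


def _corr_fixture(x_rows, y_rows, groups):
    genes = [f"g{i}" for i in range(len(x_rows))]
    expr = make_expression(np.asarray(x_rows, float), genes=genes)
    layer = pd.DataFrame(np.asarray(y_rows, float), index=genes,
                         columns=expr.samples)
    samp = make_samples(groups, sample_ids=expr.samples)
    return expr, layer, samp


def test_spearman_hand_computed():
    """x=[1,2,3], y=[3,1,2]: d^2 sum = 6, rho = 1 - 6*6/(3*8) = -0.5."""
    expr, layer, samp = _corr_fixture([[1, 2, 3]], [[3, 1, 2]],
                                      ["TNBC", "TNBC", "TNBC"])
    table = reg.spearman_by_group(expr, layer, samp, regulator="CNA")
    rho = table.loc[(table.group == "TNBC"), "rho"].iloc[0]
    assert rho == pytest.approx(-0.5, rel=1e-12)


def test_spearman_monotone_invariance_and_constant(caplog):
    x = [[1.0, 2.0, 5.0, 9.0]]
    expr, layer, samp = _corr_fixture(x, [[3.0, 5.0, 11.0, 19.0]],  # y = 2x+1
                                      ["TNBC"] * 4)
    table = reg.spearman_by_group(expr, layer, samp, regulator="CNA")
    assert table.loc[table.group == "TNBC", "rho"].iloc[0] == pytest.approx(1.0)

    expr2, layer2, samp2 = _corr_fixture(x, [[2.0, 2.0, 2.0, 2.0]], ["TNBC"] * 4)
    with caplog.at_level("WARNING"):
        t2 = reg.spearman_by_group(expr2, layer2, samp2, regulator="CNA")
    assert np.isnan(t2.loc[t2.group == "TNBC", "rho"].iloc[0])
    assert "constant" in caplog.text


def test_no_shared_samples_is_hard_error():
    expr, layer, samp = _corr_fixture([[1, 2, 3]], [[1, 2, 3]], ["TNBC"] * 3)
    layer.columns = ["z0", "z1", "z2"]
    with pytest.raises(ValueError, match="no shared samples"):
        reg.spearman_by_group(expr, layer, samp, regulator="CNA")


@pytest.mark.parametrize("rho, regulator, expected_class, expected_flag", [
    (0.450, "CNA", "strong", True),
    (0.449, "CNA", "moderate", True),
    (0.300, "CNA", "moderate", True),
    (0.299, "CNA", "weak", True),
    (0.100, "CNA", "weak", True),
    (0.099, "CNA", "low/no", True),
    (-0.05, "DM", "low/no", True),     # negative DM correlation: sign-consistent
    (0.45, "DM", "strong", False),     # positive DM correlation: flagged
    (-1.0, "CNA", "strong", False),
])
def test_strength_boundaries(rho, regulator, expected_class, expected_flag):
    cls, flag = reg.classify_strength(rho, regulator)
    assert cls == expected_class and flag == expected_flag


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
def test_strength_classes_partition_the_range(rho):
    cls, _ = reg.classify_strength(rho)
    assert cls in {"strong", "moderate", "weak", "low/no"}
    a = abs(rho)
    expected = ("strong" if a >= 0.45 else "moderate" if a >= 0.3
                else "weak" if a >= 0.1 else "low/no")
    assert cls == expected


def _rho_table(records):
    return pd.DataFrame(records, columns=["gene", "group", "regulator", "rho",
                                          "n", "strength", "sign_consistent"])


def test_delta_cor_arithmetic_and_symmetry():
    t = _rho_table([
        ("a", "TNBC", "CNA", 0.5, 10, None, None),
        ("a", "non-TNBC", "CNA", 0.2, 10, None, None),
        ("b", "TNBC", "CNA", 0.7, 10, None, None),
        ("b", "non-TNBC", "CNA", 0.7, 10, None, None),
        ("c", "TNBC", "CNA", -0.4, 10, None, None),
        ("c", "non-TNBC", "CNA", 0.6, 10, None, None),
    ])
    d = reg.delta_cor(t).set_index("gene")["delta_cor"]
    assert d["a"] == pytest.approx(0.3)
    assert d["b"] == pytest.approx(0.0)
    assert d["c"] == pytest.approx(1.0)
    # swap the groups: identical deltas
    swapped = t.copy()
    swapped["group"] = swapped["group"].map({"TNBC": "non-TNBC", "non-TNBC": "TNBC"})
    pd.testing.assert_series_equal(d, reg.delta_cor(swapped).set_index("gene")["delta_cor"])


def test_delta_cor_missing_group_logged(caplog):
    t = _rho_table([("a", "TNBC", "CNA", 0.5, 10, None, None)])
    with caplog.at_level("WARNING"):
        d = reg.delta_cor(t)
    assert d.empty and "missing group correlation" in caplog.text


def test_mann_whitney_exact_enumeration_example():
    """TNBC rhos {0.9, 0.8} vs non-TNBC {0.1, 0.2}: maximal U = 4, exact
    two-sided p = 2/C(4,2) = 1/3."""
    t = _rho_table([
        ("a", "TNBC", "CNA", 0.9, 10, None, None),
        ("a", "non-TNBC", "CNA", 0.1, 10, None, None),
        ("b", "TNBC", "CNA", 0.8, 10, None, None),
        ("b", "non-TNBC", "CNA", 0.2, 10, None, None),
    ])
    res = reg.test_differential_regulation(t)
    assert res.loc[0, "statistic"] == pytest.approx(4.0)
    assert res.loc[0, "p"] == pytest.approx(1 / 3, rel=1e-12)


def test_identical_rho_sets_give_p_one():
    t = _rho_table([
        ("a", "TNBC", "CNA", 0.4, 10, None, None),
        ("a", "non-TNBC", "CNA", 0.4, 10, None, None),
        ("b", "TNBC", "CNA", 0.4, 10, None, None),
        ("b", "non-TNBC", "CNA", 0.4, 10, None, None),
    ])
    res = reg.test_differential_regulation(t)
    assert res.loc[0, "p"] == pytest.approx(1.0)


def test_null_rejection_rate_near_nominal():
    """Identically distributed per-gene correlations: the Mann-Whitney
    rejects at ~ the nominal 5% level."""
    rng = np.random.default_rng(12)
    n_sim, n_genes, rejections = 2000, 15, 0
    from scipy import stats
    for _ in range(n_sim):
        a = rng.uniform(-1, 1, n_genes)
        b = rng.uniform(-1, 1, n_genes)
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rejections += p < 0.05
    rate = rejections / n_sim
    assert abs(rate - 0.05) < 0.02


def test_small_grouping_skipped(caplog):
    t = _rho_table([("a", "TNBC", "CNA", 0.4, 10, None, None),
                    ("a", "non-TNBC", "CNA", 0.2, 10, None, None)])
    with caplog.at_level("WARNING"):
        res = reg.test_differential_regulation(t, pathway_genes={"p1": ["a"]})
    assert res.empty and "skipped" in caplog.text


def test_driver_classes_separate_by_correlation_profile():
    """CNA-driven genes correlate with CNA, DM-driven with DM, with a
    mean absolute-correlation margin of at least 0.2 between the two
    regulator profiles (alpha=1, noise_sd=0.5, n=150/group)."""
    from glycoreg.synthetic_data import SimulationConfig, simulate_cohorts

    cfg = SimulationConfig(seed=2, noise_sd=0.5, n_per_group=150,
                           n_cna_driven=8, n_dm_driven=8, cna_alpha=1.0)
    cohorts, truth = simulate_cohorts(cfg)
    c = cohorts[0]
    genes = truth.cna_driven + truth.dm_driven
    tabs = [reg.spearman_by_group(c.expression, layer, c.samples,
                                  regulator=name, genes=genes)
            for name, layer in (("CNA", c.cna), ("DM", c.dm))]
    piv = (pd.concat(tabs)[lambda d: d.group == "all"]
           .pivot_table(index="gene", columns="regulator", values="rho"))
    cna_margin = (piv.loc[truth.cna_driven, "CNA"].abs().mean()
                  - piv.loc[truth.cna_driven, "DM"].abs().mean())
    dm_margin = (piv.loc[truth.dm_driven, "DM"].abs().mean()
                 - piv.loc[truth.dm_driven, "CNA"].abs().mean())
    assert cna_margin >= 0.2 and dm_margin >= 0.2
    # DM coupling is repressive: negative correlations for dm-driven genes
    assert (piv.loc[truth.dm_driven, "DM"] < 0).all()


def test_top_delta_cor_report():
    rows = []
    for i in range(12):
        rows.append((f"g{i}", "TNBC", "CNA", min(0.05 * i, 1.0), 10, None, None))
        rows.append((f"g{i}", "non-TNBC", "CNA", 0.0, 10, None, None))
    d = reg.delta_cor(_rho_table(rows))
    top = reg.top_delta_cor(d, k=10)
    assert len(top) == 10
    assert top["delta_cor"].iloc[0] == d["delta_cor"].max()
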