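import numpy as np
import pandas as pd
import pytest

from glycoreg.io_formats import ExpressionMatrix, SampleTable


def make_expression(values, genes=None, samples=None, dataset_id="D1"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), dataset_id=dataset_id
    )


def make_samples(groups, sample_ids=None, dataset_id="D1"):
    sample_ids = sample_ids or [f"s{i}" for i in range(len(groups))]
    return SampleTable(pd.DataFrame({
        "sample_id": sample_ids, "group": list(groups), "dataset_id": dataset_id,
    }))


@pytest.fixture(scope="session")
def two_group_cohort():
    """A 25-gene, 8+6-sample two-group expression fixture with mild DE."""
    rng = np.random.default_rng(42)
    n_genes, na, nb = 25, 8, 6
    X = rng.normal(7, 1, size=(n_genes, na + nb))
    X[:5, :na] += 2.0  # first 5 genes up in group A
    cols = [f"T{i}" for i in range(na)] + [f"N{i}" for i in range(nb)]
    expr = make_expression(X, samples=cols)
    samp = make_samples(["TNBC"] * na + ["non-TNBC"] * nb, sample_ids=cols)
    return expr, samp
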