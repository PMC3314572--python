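import numpy as np
import pytest

from modlda import ExpressionDataset


def make_dataset(values, labels=None):
    """Small helper: wrap a p x n array with generated gene/sample IDs."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    if labels is None:
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return ExpressionDataset(
        values,
        tuple(f"g{i}" for i in range(p)),
        tuple(f"s{j}" for j in range(n)),
        np.array(labels, dtype=object),
    )


def probe_like(train, values, labels=None):
    """A new-sample dataset sharing the training dataset's gene IDs."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if labels is None:
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return ExpressionDataset(
        values,
        train.gene_ids,
        tuple(f"new{j}" for j in range(n)),
        np.array(labels, dtype=object),
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
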