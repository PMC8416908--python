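import numpy as np
import pytest

from rgnb.data_model import CountMatrix, CovariateMatrix, LabelVector


@pytest.fixture
def toy_counts() -> CountMatrix:
    return CountMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2"],
        counts=np.array([[1, 2], [3, 4], [5, 6]]),
    )


@pytest.fixture
def toy_covars() -> CovariateMatrix:
    return CovariateMatrix(
        sample_ids=["s1", "s2"],
        feature_names=["f1", "f2"],
        values=np.array([[0.1, 1.0], [0.2, -1.0]]),
    )


@pytest.fixture
def toy_labels() -> LabelVector:
    return LabelVector(sample_ids=["s1", "s2"], labels=["a", "b"], class_set=["a", "b"])


def random_dataset(rng, n_genes=8, n_per_class=(10, 12), mu_range=(5, 60)):
    """Small random aligned (counts, labels) pair for property tests."""
    n = sum(n_per_class)
    counts = rng.integers(mu_range[0], mu_range[1], size=(n_genes, n))
    gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{i}" for i in range(n)]
    labels = ["a"] * n_per_class[0] + ["b"] * n_per_class[1]
    return (
        CountMatrix(gene_ids, sample_ids, counts),
        LabelVector(sample_ids, labels, ["a", "b"]),
    )
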