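import numpy as np
import pytest

from salpvote import ExpressionDataset, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 samples x 120 genes, 5 informative / 10 redundant, strong signal."""
    dataset, truth = generate_dataset(
        SyntheticSpec(n_samples=60, n_genes=120, n_informative=5, n_redundant=10, seed=1)
    )
    return dataset, truth


@pytest.fixture(scope="session")
def noise_dataset():
    """100 pure-noise genes: labels carry no information about any gene."""
    rng = np.random.default_rng(13)
    X = rng.normal(0, 1, (60, 100))
    y = np.repeat([0, 1, 2], 20)
    return ExpressionDataset(
        values=X,
        gene_ids=[f"n{i:03d}" for i in range(100)],
        sample_ids=[f"s{i:03d}" for i in range(60)],
        labels=y,
    )


def make_labelled_dataset(class_counts, n_genes=6, seed=0):
    """Pure-noise dataset with exact per-class sample counts."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(c, k) for k, c in enumerate(class_counts)])
    n = len(labels)
    return ExpressionDataset(
        values=rng.normal(size=(n, n_genes)),
        gene_ids=[f"g{j}" for j in range(n_genes)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
    )
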