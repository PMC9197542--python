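import numpy as np
import pandas as pd
import pytest

from dmespca.io import ExpressionMatrix, GeneNetwork, SubtypeLabels
from dmespca.synthetic_data import SyntheticSpec, generate, small_worked_instance


@pytest.fixture(scope="session")
def worked_instance():
    return small_worked_instance()


@pytest.fixture(scope="session")
def small_bench():
    """A light planted-module instance: 4 subtypes x 10, 80 genes, module 8."""
    spec = SyntheticSpec(
        n_genes=80,
        n_samples=40,
        subtype_sizes=[10, 10, 10, 10],
        module_size=8,
        module_extra_edges=4,
        effect=5.0,
        noise_sd=1.0,
        background_edges=150,
        seed=7,
    )
    return generate(spec)


@pytest.fixture()
def tiny_expression():
    return ExpressionMatrix(
        gene_ids=["A", "B", "C"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


def random_instance(seed, m=30, n=20, n_edges=60):
    """A random dense-ish expression matrix plus a random simple network."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(m)]
    samples = [f"s{i:02d}" for i in range(n)]
    values = rng.normal(6.0, 1.0, (m, n))
    # a couple of low-rank spikes so the leading structure is non-trivial
    for _ in range(2):
        a = rng.normal(size=m)
        b = rng.normal(size=n)
        values += 0.8 * np.outer(a, b) / np.sqrt(m)
    edges = set()
    while len(edges) < min(n_edges, m * (m - 1) // 2):
        i, j = rng.integers(0, m, 2)
        if i != j:
            edges.add(tuple(sorted((genes[int(i)], genes[int(j)]))))
    X = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
    return X, GeneNetwork(edges=sorted(edges))


def as_frame(X: ExpressionMatrix) -> pd.DataFrame:
    """Samples x genes orientation used by the estimators."""
    return pd.DataFrame(X.values.T, index=X.sample_ids, columns=X.gene_ids)
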