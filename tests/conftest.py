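import numpy as np
import pytest

from pertdeconv.data_io import (
    DigitalMixture,
    ExpressionTable,
    GeneIndex,
    ReferenceDistributions,
)


@pytest.fixture
def two_pop_refs() -> ReferenceDistributions:
    """Two well-separated populations over two genes."""
    return ReferenceDistributions(
        genes=GeneIndex(("g1", "g2")),
        population_names=("popA", "popB"),
        beta=np.array([[0.8, 0.2], [0.2, 0.8]]),
        totals=np.array([100.0, 100.0]),
    )


@pytest.fixture
def small_table() -> ExpressionTable:
    return ExpressionTable(
        genes=GeneIndex(("g1", "g2")),
        sample_names=("s1", "s2"),
        values=np.array([[1.5, 2.0], [3.25, 0.0]]),
    )


def make_counts(counts: np.ndarray) -> DigitalMixture:
    counts = np.atleast_2d(np.asarray(counts))
    return DigitalMixture(
        genes=GeneIndex(tuple(f"g{i + 1}" for i in range(counts.shape[1]))),
        sample_names=tuple(f"s{i + 1}" for i in range(counts.shape[0])),
        counts=counts,
    )


def make_refs(beta: np.ndarray) -> ReferenceDistributions:
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    return ReferenceDistributions(
        genes=GeneIndex(tuple(f"g{i + 1}" for i in range(beta.shape[1]))),
        population_names=tuple(f"pop{i + 1}" for i in range(beta.shape[0])),
        beta=beta,
        totals=np.full(beta.shape[0], 1000.0),
    )
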