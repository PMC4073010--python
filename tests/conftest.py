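import numpy as np
import pytest

from commclass import CountTable, DistanceMatrix, ProportionTable


@pytest.fixture
def small_counts() -> CountTable:
    return CountTable(
        ["s1", "s2", "s3"],
        ["Bacteroides", "Prevotella", "Ruminococcus"],
        np.array([[10, 0, 2], [1, 9, 0], [3, 3, 6]]),
    )


@pytest.fixture
def two_block_distance() -> DistanceMatrix:
    """Two clean blocks of 5: within 0.1, between 0.9."""
    n = 10
    d = np.full((n, n), 0.9)
    d[:5, :5] = 0.1
    d[5:, 5:] = 0.1
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"s{i}" for i in range(n)], d, "synthetic-blocks")


def random_proportions(rng: np.random.Generator, n: int, t: int) -> ProportionTable:
    x = rng.dirichlet(np.full(t, 0.5), size=n)
    return ProportionTable([f"s{i}" for i in range(n)], [f"g{j}" for j in range(t)], x)


def random_distance(rng: np.random.Generator, n: int) -> DistanceMatrix:
    x = rng.random((n, 2))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(n)], d, "euclidean")
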