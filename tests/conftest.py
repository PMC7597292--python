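import numpy as np
import pytest

from bnprune import (
    BDeuConfig,
    DiscreteDataset,
    enumerate_and_score,
    forward_sample,
    random_bn,
    table2_fixture,
)


@pytest.fixture(scope="session")
def table2():
    """The printed 4-node worked example: all 32 scored parent sets."""
    return table2_fixture()


@pytest.fixture
def two_binary_rows():
    """A single binary variable observed twice: one 0 and one 1."""
    return DiscreteDataset(names=["A"], arities=[2], rows=[[0], [1]])


@pytest.fixture(scope="session")
def score_set_factory():
    """Build a ScoreSet by BDeu-scoring data sampled from a random ground truth."""

    def make(n, max_indegree=None, N=200, seed=0, ess=1.0):
        d = n - 1 if max_indegree is None else max_indegree
        bn = random_bn(n, max_indegree=min(d, n - 1), edge_prob=0.5,
                       concentration=0.3, seed=seed)
        data = forward_sample(bn, N, seed=seed + 10_000)
        return enumerate_and_score(data, d, BDeuConfig(ess))

    return make


@pytest.fixture(scope="session")
def random_dataset_factory():
    def make(n=4, N=100, arity=2, seed=0):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, arity, size=(N, n))
        return DiscreteDataset(
            names=[f"V{i}" for i in range(n)], arities=[arity] * n, rows=rows
        )

    return make
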