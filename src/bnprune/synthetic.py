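"""Ground-truth network generation and forward sampling for testable experiments.

The generator draws a random DAG (uniform node order, independent edge
inclusion, in-degree capped), fills in conditional probability tables from a
symmetric Dirichlet, and produces multinomial data by ancestral sampling —
the standard recipe for benchmarking structure learners when the published
benchmark networks are unavailable.  A small Dirichlet concentration
(default 0.5) yields informative, skewed conditionals so that structure is
actually learnable from moderate samples.

Also houses the printed 4-node worked example: a complete 32-entry score set
(all parent sets up to in-degree 3 for four variables, sample size 5000) of
which exactly six entries are illegal under subset-score pruning.  The scores
are fixture values to one decimal place; the generating network behind them
is not published, so they are used as inputs, never re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .candidates import NodeScoreTable, ScoredParentSet, ScoreSet
from .scoring import DiscreteDataset
from .search import DAG

__all__ = [
    "CPT",
    "GroundTruthBN",
    "random_dag",
    "random_cpts",
    "forward_sample",
    "random_bn",
    "table2_fixture",
]


@dataclass(frozen=True)
class CPT:
    """Conditional distribution of one child: one probability row per parent configuration.

    ``table`` has shape ``(q, r)`` — ``q`` joint parent configurations
    (mixed-radix, lowest parent index least significant) by ``r`` child
    states; every row sums to 1.
    """

    child: int
    parents: Tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 2:
            raise ValueError("CPT table must be 2-D (configurations x states)")
        if (t < 0).any() or np.abs(t.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("each CPT row must be a probability vector")
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "parents", tuple(sorted(self.parents)))


@dataclass(frozen=True)
class GroundTruthBN:
    """A DAG plus one CPT per node; the generating model of a synthetic study."""

    dag: DAG
    cpts: Tuple[CPT, ...]
    arities: Tuple[int, ...]

    def __post_init__(self) -> None:
        for i, cpt in enumerate(self.cpts):
            if cpt.parents != self.dag.parents[i]:
                raise ValueError(
                    f"CPT parents {cpt.parents} of node {i} do not match "
                    f"DAG parents {self.dag.parents[i]}"
                )

    @property
    def n(self) -> int:
        return self.dag.n


def random_dag(n: int, max_indegree: int, edge_prob: float = 0.3, seed: int = 0) -> DAG:
    """Random DAG: uniform order, independent edges, in-degree capped.

    A uniform permutation fixes an ancestry order; each (predecessor, node)
    edge is included with probability ``edge_prob``; when more than
    ``max_indegree`` predecessors are selected, the node keeps the ones
    closest to it in the sampled order.  Acyclic by construction and
    deterministic in ``seed``.
    """
    n = int(n)
    d = int(max_indegree)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= d <= n - 1:
        raise ValueError(f"max_indegree must lie in [0, {n - 1}], got {d}")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must lie in [0, 1], got {edge_prob}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parents: List[Tuple[int, ...]] = [()] * n
    for pos in range(n):
        node = int(order[pos])
        preds = [int(order[j]) for j in range(pos)]
        chosen = [p for p in preds if rng.random() < edge_prob]
        if len(chosen) > d:
            # keep the d most recent predecessors among those selected
            chosen = chosen[len(chosen) - d:] if d else []
        parents[node] = tuple(sorted(chosen))
    return DAG(parents)


def random_cpts(
    dag: DAG,
    arities: Sequence[int],
    concentration: float = 0.5,
    seed: int = 0,
) -> GroundTruthBN:
    """Fill a DAG with CPTs drawn from a symmetric Dirichlet(``concentration``).

    Small concentrations give skewed (informative) conditionals; large ones
    approach uniform rows.  Deterministic in ``seed``.
    """
    if not concentration > 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    arities = tuple(int(a) for a in arities)
    if len(arities) != dag.n:
        raise ValueError(f"{len(arities)} arities for {dag.n} nodes")
    rng = np.random.default_rng(seed)
    cpts = []
    for i in range(dag.n):
        q = 1
        for p in dag.parents[i]:
            q *= arities[p]
        r = arities[i]
        table = rng.dirichlet([concentration] * r, size=q)
        cpts.append(CPT(child=i, parents=dag.parents[i], table=table))
    return GroundTruthBN(dag=dag, cpts=tuple(cpts), arities=arities)


def forward_sample(
    bn: GroundTruthBN,
    N: int,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
) -> DiscreteDataset:
    """Draw ``N`` joint observations by ancestral sampling in topological order."""
    N = int(N)
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(seed)
    n = bn.n
    topo = list(nx.topological_sort(bn.dag.to_networkx()))
    rows = np.zeros((N, n), dtype=np.int64)
    for i in topo:
        cpt = bn.cpts[i]
        if not cpt.parents:
            config = np.zeros(N, dtype=np.int64)
        else:
            config = np.zeros(N, dtype=np.int64)
            radix = 1
            for p in cpt.parents:
                config += radix * rows[:, p]
                radix *= bn.arities[p]
        u = rng.random(N)
        cdf = np.cumsum(cpt.table, axis=1)
        rows[:, i] = (u[:, None] > cdf[config]).sum(axis=1)
    if names is None:
        names = [f"X{i}" for i in range(n)]
    return DiscreteDataset(names=names, arities=bn.arities, rows=rows)


def random_bn(
    n: int,
    max_indegree: int = 3,
    edge_prob: float = 0.3,
    arity: int = 2,
    concentration: float = 0.5,
    seed: int = 0,
) -> GroundTruthBN:
    """Convenience: random DAG + random CPTs with uniform arity, one seed."""
    rng = np.random.default_rng(seed)
    s1, s2 = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
    dag = random_dag(n, max_indegree, edge_prob, seed=s1)
    return random_cpts(dag, [arity] * n, concentration, seed=s2)


# The printed 4-node worked example: local scores of every parent set up to
# in-degree 3, for four variables at sample size 5000, to one decimal place.
_TABLE2_SCORES: Dict[int, Dict[Tuple[int, ...], float]] = {
    0: {  # node "1"
        (): -2288.7,
        (1,): -2274.6,
        (2,): -2196.2,
        (3,): -2240.7,
        (1, 2): -2252.8,
        (1, 3): -2256.1,
        (2, 3): -2171.3,
        (1, 2, 3): -2173.5,
    },
    1: {  # node "2"
        (): -2003.7,
        (0,): -1989.6,
        (2,): -1900.7,
        (3,): -1915.1,
        (0, 2): -1903.8,
        (0, 3): -1918.3,
        (2, 3): -1849.2,
        (0, 2, 3): -1851.4,
    },
    2: {  # node "3"
        (): -2891.5,
        (0,): -2799.0,
        (1,): -2788.5,
        (3,): -2811.3,
        (0, 1): -2714.5,
        (0, 3): -2741.9,
        (1, 3): -2745.5,
        (0, 1, 3): -2692.6,
    },
    3: {  # node "4"
        (): -1951.6,
        (0,): -1903.6,
        (1,): -1862.9,
        (2,): -1871.4,
        (0, 1): -1829.5,
        (0, 2): -1846.5,
        (1, 2): -1819.9,
        (0, 1, 2): -1807.6,
    },
}


def table2_fixture() -> ScoreSet:
    """The complete 32-entry score set of the printed 4-node example.

    Variables are named "1".."4" (0-based indices internally).  Applying
    legality pruning removes exactly six entries — {2,3}, {2,4}, {2,3,4} for
    node 1 and {1,3}, {1,4}, {1,3,4} for node 2 — leaving 26 legal CPSs.
    """
    tables = [
        NodeScoreTable(
            child,
            [ScoredParentSet(parents=ps, score=s) for ps, s in d.items()],
        )
        for child, d in sorted(_TABLE2_SCORES.items())
    ]
    return ScoreSet(names=("1", "2", "3", "4"), tables=tables, max_indegree=3)
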