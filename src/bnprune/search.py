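"""DAG learning over candidate-parent-set score tables.

Given a :class:`~bnprune.candidates.ScoreSet` (per-node CPS lists with BDeu
scores), learning a maximum-score DAG is a combinatorial optimisation over
parent-set assignments subject to acyclicity.  Engines provided:

* :func:`exact_dp` — Silander–Myllymaki dynamic programming over variable
  subsets; globally optimal, ``O(n 2^n)`` memory, small ``n`` only.
* :func:`greedy_constructive` — a single constructive pass that gives each
  node its best-scoring CPS that keeps the partial graph acyclic, visiting
  nodes in descending order of potential gain.
* :func:`order_best_network` / :func:`order_local_search` — order-based
  search: given a node ordering, each node independently takes its best CPS
  among its predecessors (acyclic by construction); the local search
  hill-climbs over adjacent transpositions of random restart orders.
* :func:`brute_force_oracle` — exhaustive enumeration of every parent-set
  assignment, for cross-checking the other engines on tiny instances.

Every engine is deterministic given its inputs and seed.  Tie-breaking is
uniform throughout: higher score, then fewer parents, then lexicographically
smaller parent tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .candidates import ScoreSet
from .scoring import graph_score

__all__ = [
    "DAG",
    "Ordering",
    "SearchResult",
    "is_acyclic",
    "brute_force_oracle",
    "exact_dp",
    "greedy_constructive",
    "order_best_network",
    "order_local_search",
]

_BRUTE_FORCE_MAX_N = 5
_EXACT_DP_MAX_N = 22


@dataclass(frozen=True)
class DAG:
    """An acyclic parent-set assignment: ``parents[i]`` is node i's parent tuple."""

    parents: Tuple[Tuple[int, ...], ...]

    def __init__(self, parents: Sequence[Sequence[int]]):
        parents = tuple(tuple(sorted(int(p) for p in ps)) for ps in parents)
        object.__setattr__(self, "parents", parents)
        if not is_acyclic(self):
            raise ValueError("parent assignment contains a directed cycle")

    @property
    def n(self) -> int:
        return len(self.parents)

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parents)

    @property
    def roots(self) -> Tuple[int, ...]:
        """Nodes with no parents; every DAG has at least one."""
        return tuple(i for i, ps in enumerate(self.parents) if not ps)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        for child, ps in enumerate(self.parents):
            g.add_edges_from((p, child) for p in ps)
        return g


@dataclass(frozen=True)
class Ordering:
    """A permutation of node indices; position k precedes position k+1."""

    order: Tuple[int, ...]

    def __init__(self, order: Sequence[int]):
        order = tuple(int(v) for v in order)
        if sorted(order) != list(range(len(order))):
            raise ValueError(f"not a permutation of 0..{len(order) - 1}: {order}")
        object.__setattr__(self, "order", order)

    def __len__(self) -> int:
        return len(self.order)

    def __iter__(self):
        return iter(self.order)


@dataclass(frozen=True)
class SearchResult:
    dag: DAG
    total_score: float
    method: str
    iterations: int = 0
    restarts: int = 0
    seed: Optional[int] = None


def is_acyclic(dag) -> bool:
    """True iff the parent assignment admits a topological order."""
    parents = getattr(dag, "parents", dag)
    g = nx.DiGraph()
    g.add_nodes_from(range(len(parents)))
    for child, ps in enumerate(parents):
        g.add_edges_from((p, child) for p in ps)
    return nx.is_directed_acyclic_graph(g)


def _entry_arrays(score_set: ScoreSet):
    """Per node: (bitmask array, score array) in canonical table order."""
    masks, scores = [], []
    for t in score_set.tables:
        m = np.array(
            [sum(1 << p for p in e.parents) for e in t.entries], dtype=np.int64
        )
        s = np.array([e.score for e in t.entries], dtype=np.float64)
        masks.append(m)
        scores.append(s)
    return masks, scores


def brute_force_oracle(score_set: ScoreSet) -> SearchResult:
    """Globally optimal DAG by exhaustive enumeration of parent-set assignments.

    Every combination of one table entry per node is generated; cyclic
    assignments are eliminated with a vectorised Kahn root-removal pass.
    Exponential in the table sizes, hence restricted to ``n <= 5``.
    """
    n = score_set.n
    if n > _BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"brute force is limited to n <= {_BRUTE_FORCE_MAX_N} nodes, got {n}"
        )
    masks, scores = _entry_arrays(score_set)
    counts = [len(m) for m in masks]
    grids = np.meshgrid(*[np.arange(c) for c in counts], indexing="ij")
    choice = np.stack([g.ravel() for g in grids], axis=1)  # (C, n)
    C = choice.shape[0]
    pmask = np.empty((C, n), dtype=np.int64)
    total = np.zeros(C, dtype=np.float64)
    for i in range(n):
        pmask[:, i] = masks[i][choice[:, i]]
        total += scores[i][choice[:, i]]

    active = np.full(C, (1 << n) - 1, dtype=np.int64)
    for _ in range(n):
        for i in range(n):
            bit = 1 << i
            free = ((active & bit) != 0) & ((pmask[:, i] & active) == 0)
            active[free] ^= bit
    acyclic = active == 0
    if not acyclic.any():  # cannot happen: the all-empty assignment is acyclic
        raise RuntimeError("no acyclic assignment found")
    total[~acyclic] = -np.inf
    best_score = total.max()
    ties = np.flatnonzero(total == best_score)
    # fewest edges, then lexicographically smallest parent tuples
    entries = [score_set.tables[i].entries for i in range(n)]

    def tie_key(row: int):
        ps = tuple(entries[i][choice[row, i]].parents for i in range(n))
        return (sum(len(p) for p in ps), ps)

    row = min(ties, key=tie_key)
    dag = DAG([entries[i][choice[row, i]].parents for i in range(n)])
    return SearchResult(
        dag=dag,
        total_score=float(graph_score(score_set, dag)),
        method="brute_force",
        iterations=int(C),
    )


def exact_dp(score_set: ScoreSet) -> SearchResult:
    """Globally optimal DAG by dynamic programming over variable subsets.

    Phase 1 computes, for every node i and every subset S of the other nodes,
    the best table entry of i contained in S (a subset-minimum sweep over the
    canonical entry order, so ties resolve to fewer parents / lexicographic).
    Phase 2 finds the best network over each subset by choosing its best sink.
    """
    n = score_set.n
    if n > _EXACT_DP_MAX_N:
        raise ValueError(
            f"exact DP is limited to n <= {_EXACT_DP_MAX_N} nodes (2^n tables); "
            f"got n={n} — use order_local_search instead"
        )
    size = 1 << n
    full = size - 1
    masks_per_node, _ = _entry_arrays(score_set)

    best_idx: List[np.ndarray] = []
    best_val: List[np.ndarray] = []
    for i in range(n):
        t = score_set.tables[i]
        sentinel = len(t.entries)
        idx = np.full(size, sentinel, dtype=np.int64)
        # canonical order means a smaller entry index is always preferable
        idx[masks_per_node[i]] = np.arange(len(t.entries))
        arange = np.arange(size)
        for b in range(n):
            if b == i:
                continue
            step = 1 << b
            withb = arange[(arange & step) != 0]
            idx[withb] = np.minimum(idx[withb], idx[withb ^ step])
        vals = np.concatenate(
            [np.array([e.score for e in t.entries]), [-np.inf]]
        )
        best_idx.append(idx)
        best_val.append(vals[idx])

    M = np.full(size, -np.inf)
    M[0] = 0.0
    sink = np.full(size, -1, dtype=np.int64)
    pop = _popcount(np.arange(size))
    for k in range(1, n + 1):
        layer = np.flatnonzero(pop == k)
        for i in range(n):
            bit = 1 << i
            sel = layer[(layer & bit) != 0]
            prev = sel ^ bit
            cand = M[prev] + best_val[i][prev]
            better = cand > M[sel]
            M[sel] = np.where(better, cand, M[sel])
            sink[sel[better]] = i

    parents: List[Tuple[int, ...]] = [()] * n
    S = full
    while S:
        i = int(sink[S])
        rest = S ^ (1 << i)
        parents[i] = score_set.tables[i].entries[int(best_idx[i][rest])].parents
        S = rest
    dag = DAG(parents)
    return SearchResult(
        dag=dag, total_score=float(graph_score(score_set, dag)), method="dp"
    )


def _popcount(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    x = a.copy()
    while x.any():
        out += x & 1
        x >>= 1
    return out


def _reaches(parents: Sequence[Tuple[int, ...]], src: int, targets: set) -> bool:
    """True iff some node in ``targets`` is reachable from ``src`` (edges parent->child)."""
    children: List[List[int]] = [[] for _ in parents]
    for child, ps in enumerate(parents):
        for p in ps:
            children[p].append(child)
    stack, seen = [src], {src}
    while stack:
        v = stack.pop()
        if v in targets:
            return True
        for w in children[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def greedy_constructive(score_set: ScoreSet) -> SearchResult:
    """One constructive pass starting from each node's most likely CPS.

    Nodes are visited in descending order of potential gain (top CPS score
    minus empty-CPS score); each receives its highest-scoring CPS that keeps
    the partial graph acyclic, falling back through its sorted list.  The
    empty CPS always fits, so the pass terminates with a valid DAG that has
    at least one root node.
    """
    n = score_set.n
    gains = [
        (-(t.best.score - t.empty_score), i) for i, t in enumerate(score_set.tables)
    ]
    order = [i for _, i in sorted(gains)]
    parents: List[Tuple[int, ...]] = [() for _ in range(n)]
    for i in order:
        for e in score_set.tables[i].entries:
            # adding edges p -> i is safe unless i currently reaches some p
            if not _reaches(parents, i, set(e.parents)):
                parents[i] = e.parents
                break
    dag = DAG(parents)
    return SearchResult(
        dag=dag, total_score=float(graph_score(score_set, dag)), method="greedy"
    )


def _best_within(table, allowed_mask: int) -> Tuple[Tuple[int, ...], float]:
    """Best entry whose parents all lie in ``allowed_mask`` (canonical order scan)."""
    for e in table.entries:
        m = 0
        for p in e.parents:
            m |= 1 << p
        if m & ~allowed_mask == 0:
            return e.parents, e.score
    raise KeyError(f"node {table.child}: no entry fits predecessor mask {allowed_mask:b}")


def order_best_network(score_set: ScoreSet, order: Ordering | Sequence[int]) -> SearchResult:
    """Best DAG consistent with a node ordering.

    Each node takes its highest-scoring CPS drawn entirely from its
    predecessors in the ordering; the first node always gets the empty CPS.
    Acyclic by construction.
    """
    if not isinstance(order, Ordering):
        order = Ordering(order)
    n = score_set.n
    parents: List[Tuple[int, ...]] = [()] * n
    pred = 0
    for i in order:
        parents[i], _ = _best_within(score_set.tables[i], pred)
        pred |= 1 << i
    dag = DAG(parents)
    return SearchResult(
        dag=dag, total_score=float(graph_score(score_set, dag)), method="order"
    )


def order_local_search(
    score_set: ScoreSet,
    restarts: int = 10,
    max_iters: int = 10_000,
    seed: int = 0,
) -> SearchResult:
    """Hill-climbing over node orderings from random restarts.

    Each restart draws a uniform random ordering and repeatedly applies the
    first strictly improving adjacent transposition (swap of positions k and
    k+1, which only re-decides the two swapped nodes' parent sets) until a
    local optimum or ``max_iters`` accepted moves.  Deterministic given the
    seed; the best network over all restarts is returned.
    """
    if restarts < 1:
        raise ValueError(f"restarts must be >= 1, got {restarts}")
    rng = np.random.default_rng(seed)
    n = score_set.n
    tables = score_set.tables
    best: Optional[Tuple[float, DAG]] = None
    total_iters = 0
    for _ in range(restarts):
        order = [int(v) for v in rng.permutation(n)]
        node_parents: List[Tuple[int, ...]] = [()] * n
        node_score = [0.0] * n
        pred = 0
        for i in order:
            node_parents[i], node_score[i] = _best_within(tables[i], pred)
            pred |= 1 << i
        iters = 0
        improved = True
        while improved and iters < max_iters:
            improved = False
            pred = 0
            pred_at = []  # predecessor mask before each position
            for i in order:
                pred_at.append(pred)
                pred |= 1 << i
            for k in range(n - 1):
                a, b = order[k], order[k + 1]
                base = pred_at[k]
                # after the swap: b sees `base`, a sees `base | {b}`
                pb, sb = _best_within(tables[b], base)
                pa, sa = _best_within(tables[a], base | (1 << b))
                if sa + sb > node_score[a] + node_score[b]:
                    order[k], order[k + 1] = b, a
                    node_parents[a], node_score[a] = pa, sa
                    node_parents[b], node_score[b] = pb, sb
                    iters += 1
                    improved = True
                    break  # masks are stale after a swap; rescan from the top
        total_iters += iters
        total = sum(node_score)
        if best is None or total > best[0]:
            best = (total, DAG(node_parents))
    assert best is not None
    return SearchResult(
        dag=best[1],
        total_score=float(graph_score(score_set, best[1])),
        method="order_local_search",
        iterations=total_iters,
        restarts=restarts,
        seed=seed,
    )
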