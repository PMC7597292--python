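"""Candidate parent sets: enumeration, legality pruning, percentage pruning.

A candidate parent set (CPS) is a subset of variables considered as the
parents of one child node, paired with its local BDeu score.  With ``n``
variables and a maximum in-degree ``d`` the full enumeration holds
``n * sum_{k<=d} C(n-1, k)`` CPSs, which explodes quickly (100 variables at
in-degree 3 already give 16,180,000).

Two pruning stages shrink the per-node tables:

* **legality pruning** — a parent set cannot be part of an optimal DAG if one
  of its proper subsets scores at least as high for the same child, because
  swapping in the subset preserves acyclicity without lowering the total
  decomposable score.  Survivors are called *legal* CPSs.  This rule is
  score-safe: it never changes the optimum.
* **percentage pruning** — per node, drop the bottom ``p`` percent of the
  score-sorted legal list, keeping the top ``ceil((1 - p/100) * m)`` entries
  (never fewer than one).  The empty parent set is force-retained so that a
  search can always place a root node.  This stage trades accuracy for speed
  and is the knob the evaluation module sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

from .scoring import BDeuConfig, DiscreteDataset, bdeu_local_score

__all__ = [
    "ScoredParentSet",
    "NodeScoreTable",
    "ScoreSet",
    "count_possible_cps",
    "enumerate_and_score",
    "legal_prune",
    "percent_prune",
]


@dataclass(frozen=True)
class ScoredParentSet:
    """One CPS: a sorted parent index tuple with its local score."""

    parents: Tuple[int, ...]
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(sorted(self.parents)))

    @property
    def size(self) -> int:
        return len(self.parents)


def entry_sort_key(entry: ScoredParentSet):
    """Canonical table order: score descending, then fewer parents, then lexicographic."""
    return (-entry.score, entry.size, entry.parents)


class NodeScoreTable:
    """The CPS list of one child node, kept sorted in canonical order."""

    def __init__(self, child: int, entries: Sequence[ScoredParentSet]):
        self.child = int(child)
        entries = sorted(entries, key=entry_sort_key)
        self._lookup: Dict[Tuple[int, ...], float] = {}
        for e in entries:
            if self.child in e.parents:
                raise ValueError(
                    f"node {child} appears in its own parent set {e.parents}"
                )
            if e.parents in self._lookup:
                raise ValueError(
                    f"duplicate parent set {e.parents} for node {child}"
                )
            self._lookup[e.parents] = e.score
        self.entries: List[ScoredParentSet] = list(entries)
        if () not in self._lookup:
            raise ValueError(f"node {child}: the empty parent set must be present")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, NodeScoreTable):
            return NotImplemented
        return self.child == other.child and self.entries == other.entries

    def score_of(self, parents: Sequence[int]) -> float:
        """Score of an exact parent set; KeyError if absent."""
        return self._lookup[tuple(sorted(parents))]

    def __contains__(self, parents) -> bool:
        return tuple(sorted(parents)) in self._lookup

    @property
    def best(self) -> ScoredParentSet:
        return self.entries[0]

    @property
    def empty_score(self) -> float:
        return self._lookup[()]


@dataclass
class ScoreSet:
    """Per-network CPS collection: one :class:`NodeScoreTable` per variable."""

    names: Tuple[str, ...]
    tables: List[NodeScoreTable]
    arities: Optional[Tuple[int, ...]] = None
    max_indegree: Optional[int] = None

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if self.arities is not None:
            self.arities = tuple(self.arities)
        if len(self.tables) != len(self.names):
            raise ValueError(
                f"{len(self.names)} names but {len(self.tables)} score tables"
            )
        for i, t in enumerate(self.tables):
            if t.child != i:
                raise ValueError(f"table {i} is for child {t.child}")

    @property
    def n(self) -> int:
        return len(self.names)

    def total_entries(self) -> int:
        return sum(len(t) for t in self.tables)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScoreSet):
            return NotImplemented
        return self.names == other.names and self.tables == other.tables


def count_possible_cps(n: int, d: int) -> int:
    """Number of CPSs of an ``n``-variable problem at maximum in-degree ``d``.

    Exact integer ``n * sum_{k=0}^{d} C(n-1, k)``; e.g. 100 variables at
    in-degree 1 give 10,000 and at in-degree 3 give 16,180,000.
    """
    n = int(n)
    d = int(d)
    if n < 1:
        raise ValueError(f"need at least one variable, got n={n}")
    if d < 0 or d > n - 1:
        raise ValueError(f"max in-degree must lie in [0, {n - 1}], got {d}")
    return n * sum(math.comb(n - 1, k) for k in range(d + 1))


def enumerate_and_score(
    data: DiscreteDataset,
    max_indegree: int,
    cfg: BDeuConfig | None = None,
    legal_only: bool = False,
) -> ScoreSet:
    """Score every parent set of size ``<= max_indegree`` for every node.

    With ``legal_only`` the subset-score legality rule is applied before
    returning (requires the full enumeration, which this produces).
    """
    cfg = cfg or BDeuConfig()
    n = data.n
    d = int(max_indegree)
    if d < 0:
        raise ValueError(f"max in-degree must be >= 0, got {d}")
    d = min(d, n - 1)
    tables = []
    for child in range(n):
        others = [v for v in range(n) if v != child]
        entries = []
        for k in range(d + 1):
            for parents in combinations(others, k):
                s = bdeu_local_score(data, child, parents, cfg)
                entries.append(ScoredParentSet(parents=s.parents, score=s.value))
        tables.append(NodeScoreTable(child, entries))
    out = ScoreSet(
        names=data.names, tables=tables, arities=data.arities, max_indegree=d
    )
    if legal_only:
        out = legal_prune(out)
    return out


def _prune_table(table: NodeScoreTable) -> NodeScoreTable:
    lookup = table._lookup
    kept = []
    for e in table.entries:
        dominated = False
        if e.size > 0:
            # check every proper subset present in the table; >= prunes ties
            # (a smaller set with an equal score dominates)
            for k in range(e.size):
                for sub in combinations(e.parents, k):
                    s = lookup.get(sub)
                    if s is not None and s >= e.score:
                        dominated = True
                        break
                if dominated:
                    break
        if not dominated:
            kept.append(e)
    return NodeScoreTable(table.child, kept)


def legal_prune(score_set: ScoreSet) -> ScoreSet:
    """Remove every CPS dominated by a proper subset with a score at least as high.

    The empty set has no proper subset and is always retained.  The rule never
    changes the achievable optimum: any DAG using a pruned set can swap in the
    dominating subset without creating a cycle or lowering the total score.
    """
    return ScoreSet(
        names=score_set.names,
        tables=[_prune_table(t) for t in score_set.tables],
        arities=score_set.arities,
        max_indegree=score_set.max_indegree,
    )


def percent_prune(score_set: ScoreSet, percent: float) -> ScoreSet:
    """Drop the bottom ``percent`` of each node's sorted CPS list.

    Keeps the top ``ceil((1 - percent/100) * m)`` entries of each ``m``-entry
    table (at least one), re-appending the empty parent set whenever the cut
    would remove it, so that every node can still be a root.  ``percent=0`` is
    the identity.
    """
    p = float(percent)
    if not 0 <= p < 100:
        raise ValueError(f"percent must lie in [0, 100), got {percent}")
    if p == 0:
        return score_set
    tables = []
    for t in score_set.tables:
        m = len(t)
        keep = max(1, math.ceil((1.0 - p / 100.0) * m))
        kept = t.entries[:keep]
        if all(e.parents != () for e in kept):
            kept = kept + [ScoredParentSet((), t.empty_score)]
        tables.append(NodeScoreTable(t.child, kept))
    return ScoreSet(
        names=score_set.names,
        tables=tables,
        arities=score_set.arities,
        max_indegree=score_set.max_indegree,
    )
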