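"""Accuracy/speed trade-off of CPS pruning, and structure-space counting.

The loss in accuracy caused by pruning is measured as the discrepancy

.. math:: \\Delta = (S^* - S) / S^*

between the BDeu score :math:`S` of the graph learnt from pruned CPS tables
and the score :math:`S^*` of the baseline graph learnt without pruning.
Scores are negative, and pruning can only remove options from an exact
search, so :math:`S \\le S^*` and :math:`\\Delta \\le 0`; it is conventionally
reported in per mille (multiplied by 1000).

:func:`pruning_curve` runs the full protocol: score once, legality-prune,
then sweep percentage-pruning levels, re-learning at each level with the same
engine and seed, reporting CPS counts, scores and Δ per level.

Also here: the exact counts of the two search spaces — all labeled DAGs on n
nodes (Robinson's recurrence; super-exponential, ~4.2e18 at n=10) and all
structures consistent with node orderings (2^(n(n-1)/2), ~3.5e13 at n=10) —
which motivate order-based search in the first place.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Union

from .candidates import ScoreSet, enumerate_and_score, legal_prune, percent_prune
from .scoring import BDeuConfig, DiscreteDataset
from .search import (
    SearchResult,
    exact_dp,
    greedy_constructive,
    order_local_search,
)

__all__ = [
    "PruningCurveRecord",
    "StructureCount",
    "delta_discrepancy",
    "dag_count",
    "order_structure_count",
    "pruning_curve",
    "curve_to_tsv",
]


@dataclass(frozen=True)
class PruningCurveRecord:
    """One pruning level of a sweep: CPS counts, scores, Δ, wall time."""

    level: float
    cps_total: int
    cps_per_node: float
    S: float
    S_star: float
    delta: float
    time_to_best: float

    @property
    def delta_permille(self) -> float:
        return self.delta * 1000.0


@dataclass(frozen=True)
class StructureCount:
    """An exact big-integer count of structures for an n-node problem."""

    n: int
    value: int

    def __int__(self) -> int:
        return self.value


def delta_discrepancy(S_star: float, S: float) -> float:
    """Relative score discrepancy ``(S* - S) / S*`` (raw ratio, not per mille).

    With negative BDeu scores and a pruned score no better than the baseline
    (``S <= S* < 0``) the result is <= 0, matching the sign convention of
    per-mille Δ tables.
    """
    if S_star == 0:
        raise ValueError("baseline score S* must be nonzero")
    return (S_star - S) / S_star + 0.0  # avoid IEEE negative zero


@lru_cache(maxsize=None)
def _dag_count(m: int) -> int:
    if m == 0:
        return 1
    return sum(
        (-1) ** (i + 1) * math.comb(m, i) * 2 ** (i * (m - i)) * _dag_count(m - i)
        for i in range(1, m + 1)
    )


def dag_count(n: int) -> StructureCount:
    """Number of labeled DAGs on ``n`` nodes (Robinson's recurrence), exactly."""
    n = int(n)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return StructureCount(n=n, value=_dag_count(n))


def order_structure_count(n: int) -> StructureCount:
    """Number of structures consistent with node orderings: ``2^(n(n-1)/2)``."""
    n = int(n)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return StructureCount(n=n, value=2 ** (n * (n - 1) // 2))


_ENGINES = {"dp", "greedy", "order"}


def _run_engine(
    score_set: ScoreSet, method: str, seed: int, restarts: int, max_iters: int
) -> SearchResult:
    if method == "dp":
        return exact_dp(score_set)
    if method == "greedy":
        return greedy_constructive(score_set)
    if method == "order":
        return order_local_search(
            score_set, restarts=restarts, max_iters=max_iters, seed=seed
        )
    raise ValueError(f"unknown search method {method!r}; choose from {sorted(_ENGINES)}")


def pruning_curve(
    source: Union[ScoreSet, DiscreteDataset],
    levels: Sequence[float],
    method: str = "dp",
    seed: int = 0,
    max_indegree: int = 3,
    ess: float = 1.0,
    restarts: int = 10,
    max_iters: int = 10_000,
    apply_legality: bool = True,
) -> List[PruningCurveRecord]:
    """Sweep percentage-pruning levels and measure Δ against the unpruned baseline.

    ``source`` is either a ready :class:`ScoreSet` (assumed legality-pruned
    when ``apply_legality`` is False) or a :class:`DiscreteDataset`, in which
    case CPSs are enumerated at ``max_indegree`` and scored with BDeu(``ess``)
    first.  Level 0 is always included and defines the baseline ``S*``; the
    same engine and seed are used at every level.  Records are returned in
    ascending level order.
    """
    if isinstance(source, DiscreteDataset):
        score_set = enumerate_and_score(source, max_indegree, BDeuConfig(ess))
    else:
        score_set = source
    if apply_legality:
        score_set = legal_prune(score_set)

    lvls = sorted({float(v) for v in levels} | {0.0})
    records: List[PruningCurveRecord] = []
    S_star: Optional[float] = None
    for p in lvls:
        pruned = percent_prune(score_set, p)
        t0 = time.perf_counter()
        result = _run_engine(pruned, method, seed, restarts, max_iters)
        elapsed = time.perf_counter() - t0
        if S_star is None:  # level 0 runs first
            S_star = result.total_score
        records.append(
            PruningCurveRecord(
                level=p,
                cps_total=pruned.total_entries(),
                cps_per_node=pruned.total_entries() / pruned.n,
                S=result.total_score,
                S_star=S_star,
                delta=delta_discrepancy(S_star, result.total_score),
                time_to_best=elapsed,
            )
        )
    return records


def curve_to_tsv(records: Sequence[PruningCurveRecord]) -> str:
    """TSV rendering of a pruning sweep (Δ in per mille, 2 decimals)."""
    lines = ["level\tcps_graph\tcps_per_node\tS\tS_star\tdelta_permille\ttime_secs"]
    for r in records:
        lines.append(
            f"{r.level:g}\t{r.cps_total}\t{r.cps_per_node:.2f}\t"
            f"{r.S:.6f}\t{r.S_star:.6f}\t{r.delta_permille:.2f}\t{r.time_to_best:.3f}"
        )
    return "\n".join(lines) + "\n"
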