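"""Independent brute-force oracles used to pin expected values in tests.

Everything here recomputes quantities by direct enumeration or per-row
tallying, deliberately sharing no code path with the package internals it
checks.
"""

from __future__ import annotations

from itertools import combinations, permutations, product

import numpy as np


def tally_counts(rows, arities, child, parents):
    """Per-row contingency tally, mixed-radix config index (lowest parent least significant)."""
    counts = {}
    for row in np.asarray(rows):
        j = 0
        radix = 1
        for p in sorted(parents):
            j += radix * int(row[p])
            radix *= int(arities[p])
        key = (j, int(row[child]))
        counts[key] = counts.get(key, 0) + 1
    return counts


def count_all_dags(n: int) -> int:
    """Number of labeled DAGs on n nodes by enumerating all 2^(n(n-1)) digraphs."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    G = np.arange(1 << len(pairs), dtype=np.int64)
    pmask = np.zeros((len(G), n), dtype=np.int64)
    for b, (i, j) in enumerate(pairs):
        pmask[:, j] |= ((G >> b) & 1) << i
    active = np.full(len(G), (1 << n) - 1, dtype=np.int64)
    for _ in range(n):
        for i in range(n):
            bit = 1 << i
            free = ((active & bit) != 0) & ((pmask[:, i] & active) == 0)
            active[free] ^= bit
    return int((active == 0).sum())


def legal_survivors(table_scores: dict) -> set:
    """All-pairs subset comparison: parent sets not dominated by any proper subset.

    ``table_scores`` maps parent tuples to scores for one child.
    """
    kept = set()
    for ps, s in table_scores.items():
        dominated = any(
            qs >= s
            for q, qs in table_scores.items()
            if set(q) < set(ps)
        )
        if not dominated:
            kept.add(ps)
    return kept


def best_dag_over_orders(score_set):
    """Optimal total score via exhaustive node orderings (n! small).

    For each permutation every node independently takes its best-scoring
    entry contained in its predecessors; the max over permutations is the
    global optimum over the score tables.
    """
    n = score_set.n
    best = -np.inf
    for order in permutations(range(n)):
        pred = set()
        total = 0.0
        for i in order:
            total += max(
                e.score
                for e in score_set.tables[i].entries
                if set(e.parents) <= pred
            )
            pred.add(i)
        best = max(best, total)
    return best


def cpdag_signature(parents):
    """(skeleton, v-structures) pair identifying a Markov equivalence class."""
    edges = {(p, c) for c, ps in enumerate(parents) for p in ps}
    skeleton = {frozenset(e) for e in edges}
    vstructs = set()
    for c, ps in enumerate(parents):
        for a, b in combinations(sorted(ps), 2):
            if frozenset((a, b)) not in skeleton:
                vstructs.add((frozenset((a, b)), c))
    return frozenset(skeleton), frozenset(vstructs)
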