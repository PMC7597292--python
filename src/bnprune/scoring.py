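"""BDeu local scores for discrete Bayesian networks.

The BDeu (Bayesian Dirichlet equivalent uniform) score of a child variable
:math:`X_i` with parent set :math:`\\Pi_i` is the log marginal likelihood of
the child's column under a symmetric Dirichlet prior whose total mass
:math:`\\alpha` (the equivalent sample size, ESS) is spread uniformly over the
:math:`q_i \\cdot r_i` cells of the conditional probability table:

.. math::

    \\mathrm{BDeu}(X_i, \\Pi_i) =
        \\sum_{j=1}^{q_i} \\Big[ \\ln\\Gamma(\\tfrac{\\alpha}{q_i})
            - \\ln\\Gamma(\\tfrac{\\alpha}{q_i} + N_{ij}) \\Big]
        + \\sum_{j=1}^{q_i} \\sum_{k=1}^{r_i}
          \\Big[ \\ln\\Gamma(\\tfrac{\\alpha}{q_i r_i} + N_{ijk})
            - \\ln\\Gamma(\\tfrac{\\alpha}{q_i r_i}) \\Big]

where :math:`r_i` is the child's arity, :math:`q_i` the number of joint parent
configurations (the product of parent arities, counting configurations that
never occur in the data), :math:`N_{ijk}` the number of rows with the child in
state ``k`` and the parents in configuration ``j``, and
:math:`N_{ij} = \\sum_k N_{ijk}`.

The score is decomposable: the score of a DAG is the sum of the local scores
of each node's assigned parent set, which is what makes candidate-parent-set
based combinatorial search possible.  It is also score (Markov) equivalent:
DAGs encoding the same conditional independencies receive the same total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DiscreteDataset",
    "BDeuConfig",
    "ContingencyTable",
    "LocalScore",
    "contingency_counts",
    "bdeu_local_score",
    "graph_score",
]


@dataclass(frozen=True)
class DiscreteDataset:
    """Named discrete variables with an ``N x n`` integer observation matrix.

    Parameters
    ----------
    names
        Unique variable identifiers, one per column.
    arities
        Number of states ``r_i >= 2`` of each variable.  Values in column
        ``i`` must lie in ``[0, r_i)``.
    rows
        Integer observation matrix with one row per sample.
    """

    names: Tuple[str, ...]
    arities: Tuple[int, ...]
    rows: np.ndarray = field(repr=False)

    def __init__(self, names: Sequence[str], arities: Sequence[int], rows) -> None:
        names = tuple(str(v) for v in names)
        arities = tuple(int(a) for a in arities)
        rows = np.asarray(rows, dtype=np.int64)
        if rows.ndim != 2:
            raise ValueError(f"rows must be a 2-D matrix, got ndim={rows.ndim}")
        n = rows.shape[1]
        if len(names) != n or len(arities) != n:
            raise ValueError(
                f"got {len(names)} names and {len(arities)} arities "
                f"for {n} data columns"
            )
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if rows.shape[0] < 1:
            raise ValueError("dataset must contain at least one row")
        for i, r in enumerate(arities):
            if r < 2:
                raise ValueError(f"arity of variable {names[i]!r} must be >= 2, got {r}")
            col = rows[:, i]
            if col.min() < 0 or col.max() >= r:
                raise ValueError(
                    f"values of variable {names[i]!r} must lie in [0, {r})"
                )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "arities", arities)
        object.__setattr__(self, "rows", rows)

    @property
    def n(self) -> int:
        """Number of variables."""
        return self.rows.shape[1]

    @property
    def N(self) -> int:
        """Number of observations."""
        return self.rows.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiscreteDataset):
            return NotImplemented
        return (
            self.names == other.names
            and self.arities == other.arities
            and np.array_equal(self.rows, other.rows)
        )


@dataclass(frozen=True)
class BDeuConfig:
    """Scoring configuration: the equivalent sample size ``ess`` (alpha > 0)."""

    ess: float = 1.0

    def __post_init__(self) -> None:
        if not self.ess > 0:
            raise ValueError(f"ess must be positive, got {self.ess}")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts ``N_ijk`` of a child variable against its parent configurations.

    ``q`` counts *all* joint parent configurations (the product of parent
    arities), including configurations never observed; ``counts`` maps
    ``(parent configuration index j, child state k)`` to ``N_ijk`` and omits
    zero cells.  The configuration index is the mixed-radix encoding of the
    parent values with the lowest parent index as the least significant digit.
    """

    child: int
    parents: Tuple[int, ...]
    q: int
    r: int
    counts: Mapping[Tuple[int, int], int]

    @property
    def N(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True, order=True)
class LocalScore:
    """A (child, parent set) pair with its natural-log BDeu score."""

    child: int
    parents: Tuple[int, ...]
    value: float


def _validate_family(data: DiscreteDataset, child: int, parents: Iterable[int]) -> Tuple[int, ...]:
    n = data.n
    if not 0 <= child < n:
        raise IndexError(f"child index {child} out of range for {n} variables")
    parents = tuple(sorted(int(p) for p in parents))
    for p in parents:
        if not 0 <= p < n:
            raise IndexError(f"parent index {p} out of range for {n} variables")
    if child in parents:
        raise ValueError(f"child {child} cannot be its own parent")
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parent indices")
    return parents


def _config_index(data: DiscreteDataset, parents: Tuple[int, ...]) -> np.ndarray:
    """Mixed-radix parent-configuration index per row (lowest index = least significant)."""
    idx = np.zeros(data.N, dtype=np.int64)
    radix = 1
    for p in parents:
        idx += radix * data.rows[:, p]
        radix *= data.arities[p]
    return idx


def contingency_counts(
    data: DiscreteDataset, child: int, parents: Iterable[int] = ()
) -> ContingencyTable:
    """Tally ``N_ijk`` for a (child, parent set) family.

    With an empty parent set there is a single configuration ``j = 0`` and the
    counts reduce to the child's marginal tally.
    """
    parents = _validate_family(data, child, parents)
    r = data.arities[child]
    q = 1
    for p in parents:
        q *= data.arities[p]
    j = _config_index(data, parents)
    k = data.rows[:, child]
    flat = np.bincount(j * r + k, minlength=0)
    counts = {
        (int(cell // r), int(cell % r)): int(c)
        for cell, c in enumerate(flat)
        if c > 0
    }
    return ContingencyTable(child=child, parents=parents, q=q, r=r, counts=counts)


def bdeu_local_score(
    data: DiscreteDataset,
    child: int,
    parents: Iterable[int] = (),
    cfg: BDeuConfig | None = None,
) -> LocalScore:
    """BDeu log marginal likelihood of ``child`` given ``parents``.

    Configurations with ``N_ij = 0`` contribute nothing to the sums, so only
    observed parent configurations are visited; ``q`` in the hyperparameters
    nevertheless counts all configurations.
    """
    cfg = cfg or BDeuConfig()
    parents = _validate_family(data, child, parents)
    r = data.arities[child]
    q = 1
    for p in parents:
        q *= data.arities[p]
    a_j = cfg.ess / q
    a_jk = cfg.ess / (q * r)

    j = _config_index(data, parents)
    # collapse to observed configurations only; unobserved ones contribute 0
    _, inv = np.unique(j, return_inverse=True)
    m = inv.max() + 1
    njk = np.bincount(inv * r + data.rows[:, child], minlength=m * r).reshape(m, r)
    nj = njk.sum(axis=1)

    value = float(
        np.sum(gammaln(a_j) - gammaln(a_j + nj))
        + np.sum(gammaln(a_jk + njk) - gammaln(a_jk))
    )
    return LocalScore(child=child, parents=parents, value=value)


def graph_score(score_set, dag) -> float:
    """Total decomposable score of a DAG: the sum of its nodes' local scores.

    Parameters
    ----------
    score_set
        A :class:`~bnprune.candidates.ScoreSet` holding one score table per node.
    dag
        Object with a ``parents`` sequence (parent tuple per node), or a plain
        sequence of parent tuples.

    Raises
    ------
    KeyError
        If some node's assigned parent set has no entry in ``score_set``,
        naming the offending node.
    """
    assignment = getattr(dag, "parents", dag)
    total = 0.0
    for node, parents in enumerate(assignment):
        parents = tuple(sorted(parents))
        table = score_set.tables[node]
        try:
            total += table.score_of(parents)
        except KeyError:
            raise KeyError(
                f"no score entry for node {score_set.names[node]!r} "
                f"with parent set {parents}"
            ) from None
    return total
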