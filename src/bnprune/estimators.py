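"""Scikit-learn-style estimator facade over the structure-learning pipeline."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .candidates import enumerate_and_score, legal_prune, percent_prune
from .evaluation import delta_discrepancy
from .scoring import BDeuConfig, DiscreteDataset, graph_score
from .search import exact_dp, greedy_constructive, order_local_search

__all__ = ["BNStructureLearner"]


class BNStructureLearner(BaseEstimator):
    """Learn a discrete Bayesian network structure from an integer data matrix.

    The pipeline is: enumerate candidate parent sets up to ``max_indegree``,
    score them with BDeu(``ess``), legality-prune (drop every parent set
    dominated by a proper subset with a score at least as high), optionally
    drop the bottom ``prune_percent`` of each node's sorted list, then run the
    selected search engine over the surviving tables.

    Parameters
    ----------
    max_indegree : int, default 3
        Largest parent set considered per node.
    ess : float, default 1.0
        BDeu equivalent sample size (Dirichlet prior mass).
    prune_percent : float, default 0.0
        Percentage of each node's sorted legal CPS list to discard, bottom
        first; the empty parent set is always retained.
    method : {"dp", "greedy", "order"}, default "dp"
        Search engine: exact dynamic programming, one greedy constructive
        pass, or order-based local search with restarts.
    restarts, max_iters : int
        Order-based search budget (ignored by the other engines).
    random_state : int, default 0
        Seed for the order-based engine's restart orders.

    Attributes
    ----------
    score_set_ : ScoreSet
        The pruned per-node score tables the search ran on.
    dag_ : DAG
        The learned structure (parent tuple per node).
    total_score_ : float
        Its total BDeu score (sum of local scores).
    names_ : tuple of str
        Variable names (``X0..X{n-1}`` when fitted from a bare matrix).
    n_features_in_ : int

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> a = rng.integers(0, 2, 500); b = (a + rng.integers(0, 2, 500)) % 2
    >>> learner = BNStructureLearner(max_indegree=1).fit(np.c_[a, b])
    >>> learner.dag_.n_edges
    1
    """

    def __init__(
        self,
        max_indegree: int = 3,
        ess: float = 1.0,
        prune_percent: float = 0.0,
        method: str = "dp",
        restarts: int = 10,
        max_iters: int = 10_000,
        random_state: int = 0,
    ):
        self.max_indegree = max_indegree
        self.ess = ess
        self.prune_percent = prune_percent
        self.method = method
        self.restarts = restarts
        self.max_iters = max_iters
        self.random_state = random_state

    def _as_dataset(self, X) -> DiscreteDataset:
        if isinstance(X, DiscreteDataset):
            return X
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError(f"expected a 2-D data matrix, got shape {X.shape}")
        if not np.issubdtype(X.dtype, np.integer):
            Xf = np.asarray(X, dtype=float)
            if not np.allclose(Xf, np.round(Xf)):
                raise ValueError("data must be integer-coded discrete states")
            X = Xf.astype(np.int64)
        arities = [max(2, int(X[:, i].max()) + 1) for i in range(X.shape[1])]
        names = [f"X{i}" for i in range(X.shape[1])]
        return DiscreteDataset(names=names, arities=arities, rows=X)

    def fit(self, X, y=None):
        """Learn the structure from ``X`` (n_samples x n_features integer states)."""
        data = self._as_dataset(X)
        score_set = enumerate_and_score(
            data, self.max_indegree, BDeuConfig(self.ess), legal_only=True
        )
        score_set = percent_prune(score_set, self.prune_percent)
        if self.method == "dp":
            result = exact_dp(score_set)
        elif self.method == "greedy":
            result = greedy_constructive(score_set)
        elif self.method == "order":
            result = order_local_search(
                score_set,
                restarts=self.restarts,
                max_iters=self.max_iters,
                seed=self.random_state,
            )
        else:
            raise ValueError(
                f"unknown method {self.method!r}; choose 'dp', 'greedy' or 'order'"
            )
        self.score_set_ = score_set
        self.dag_ = result.dag
        self.total_score_ = result.total_score
        self.search_result_ = result
        self.names_ = data.names
        self.n_features_in_ = data.n
        return self

    def score(self, X=None, y=None) -> float:
        """BDeu score of the learned DAG; on new data ``X``, rescored against it."""
        check_is_fitted(self, "dag_")
        if X is None:
            return self.total_score_
        data = self._as_dataset(X)
        if data.n != self.n_features_in_:
            raise ValueError(
                f"X has {data.n} features, fitted with {self.n_features_in_}"
            )
        cfg = BDeuConfig(self.ess)
        from .scoring import bdeu_local_score

        return sum(
            bdeu_local_score(data, i, self.dag_.parents[i], cfg).value
            for i in range(data.n)
        )

    def delta_vs(self, baseline_score: float) -> float:
        """Δ = (S* − S)/S* of this fit against a baseline score, as a raw ratio."""
        check_is_fitted(self, "total_score_")
        return delta_discrepancy(baseline_score, self.total_score_)

    def edges_(self) -> list:
        """Learned edges as (parent name, child name) pairs."""
        check_is_fitted(self, "dag_")
        return [
            (self.names_[p], self.names_[c])
            for c, ps in enumerate(self.dag_.parents)
            for p in ps
        ]
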