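import itertools

import numpy as np
import pytest

from bnprune import (
    DAG,
    NodeScoreTable,
    Ordering,
    ScoredParentSet,
    ScoreSet,
    brute_force_oracle,
    exact_dp,
    greedy_constructive,
    is_acyclic,
    legal_prune,
    order_best_network,
    order_local_search,
    percent_prune,
    random_dag,
)

from _oracles import best_dag_over_orders


def _toy_score_set(node_tables):
    """node_tables: list of {parents: score} dicts."""
    tables = [
        NodeScoreTable(i, [ScoredParentSet(ps, s) for ps, s in d.items()])
        for i, d in enumerate(node_tables)
    ]
    return ScoreSet(names=tuple(f"N{i}" for i in range(len(tables))), tables=tables)


class TestAcyclicity:
    def test_empty_graph_is_acyclic(self):
        assert is_acyclic([(), (), (), ()])

    def test_two_cycle_is_not(self):
        assert not is_acyclic([(1,), (0,)])

    def test_dag_constructor_rejects_cycles(self):
        with pytest.raises(ValueError):
            DAG([(2,), (0,), (1,)])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_dag_generator_contract(self, seed):
        dag = random_dag(8, max_indegree=3, edge_prob=0.6, seed=seed)
        assert is_acyclic(dag)
        assert max(len(ps) for ps in dag.parents) <= 3
        assert len(dag.roots) >= 1

    def test_ordering_validates_permutation(self):
        with pytest.raises(ValueError):
            Ordering([0, 0, 1])


class TestBruteForceOracle:
    def test_empty_best_everywhere_gives_empty_graph(self):
        ss = _toy_score_set([
            {(): -1.0, (1,): -2.0},
            {(): -1.0, (0,): -2.0},
        ])
        res = brute_force_oracle(ss)
        assert res.dag.parents == ((), ())
        assert res.total_score == pytest.approx(-2.0)

    def test_worked_example_optimum_uses_only_legal_cps(self, table2):
        res = brute_force_oracle(table2)
        legal = legal_prune(table2)
        for i, ps in enumerate(res.dag.parents):
            assert ps in legal.tables[i]

    def test_rejects_large_problems(self, score_set_factory):
        ss = score_set_factory(n=6, max_indegree=1, N=50, seed=0)
        with pytest.raises(ValueError):
            brute_force_oracle(ss)


class TestExactDP:
    def test_agrees_with_brute_force_on_worked_example(self, table2):
        assert exact_dp(table2).total_score == pytest.approx(
            brute_force_oracle(table2).total_score
        )

    @pytest.mark.parametrize("n,seed", [(3, 1), (4, 2), (4, 3), (5, 4)])
    def test_agrees_with_brute_force_on_random_instances(self, score_set_factory, n, seed):
        ss = score_set_factory(n=n, max_indegree=min(n - 1, 2), N=150, seed=seed)
        assert exact_dp(ss).total_score == pytest.approx(
            brute_force_oracle(ss).total_score, rel=1e-12
        )

    def test_agrees_with_exhaustive_order_enumeration(self, score_set_factory):
        ss = score_set_factory(n=4, N=120, seed=9)
        assert exact_dp(ss).total_score == pytest.approx(
            best_dag_over_orders(ss), rel=1e-12
        )

    def test_legality_pruning_preserves_the_optimum(self, table2):
        assert exact_dp(legal_prune(table2)).total_score == pytest.approx(
            exact_dp(table2).total_score
        )

    def test_percent_prune_zero_is_identity_for_search(self, table2):
        assert exact_dp(percent_prune(table2, 0)).total_score == pytest.approx(
            exact_dp(table2).total_score
        )

    def test_optimum_nonincreasing_in_pruning_level(self, score_set_factory):
        ss = legal_prune(score_set_factory(n=6, max_indegree=2, N=400, seed=11))
        totals = [exact_dp(percent_prune(ss, p)).total_score for p in (0, 30, 60, 90)]
        assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_result_invariants(self, score_set_factory):
        ss = score_set_factory(n=5, max_indegree=2, N=100, seed=13)
        res = exact_dp(ss)
        assert is_acyclic(res.dag)
        assert len(res.dag.roots) >= 1


class TestGreedyConstructive:
    def test_empty_best_everywhere_matches_exact(self):
        ss = _toy_score_set([
            {(): -1.0, (1,): -5.0},
            {(): -1.0, (0,): -5.0},
        ])
        res = greedy_constructive(ss)
        assert res.dag.parents == ((), ())
        assert res.total_score == pytest.approx(exact_dp(ss).total_score)

    def test_mutual_best_resolves_one_way(self):
        # both nodes want the other as parent; the first processed wins and
        # the other falls back to its next acyclic choice (the empty set)
        ss = _toy_score_set([
            {(): -5.0, (1,): -1.0},
            {(): -5.0, (0,): -1.0},
        ])
        res = greedy_constructive(ss)
        assert res.dag.parents == ((1,), ())
        assert res.total_score == pytest.approx(-6.0)

    def test_bounded_by_exact_optimum(self, table2, score_set_factory):
        for ss in (table2, score_set_factory(n=5, N=200, seed=21)):
            res = greedy_constructive(ss)
            assert is_acyclic(res.dag)
            assert res.total_score <= exact_dp(ss).total_score + 1e-9


class TestOrderBestNetwork:
    def test_first_node_gets_empty_cps(self, table2):
        res = order_best_network(table2, [2, 0, 1, 3])
        assert res.dag.parents[2] == ()

    def test_max_over_all_orders_equals_exact_optimum(self, table2):
        best = max(
            order_best_network(table2, list(o)).total_score
            for o in itertools.permutations(range(4))
        )
        assert best == pytest.approx(exact_dp(table2).total_score)

    def test_edgeless_optimal_set_is_order_invariant(self):
        ss = _toy_score_set([
            {(): -1.0, (1,): -9.0},
            {(): -1.0, (0,): -9.0},
        ])
        a = order_best_network(ss, [0, 1]).total_score
        b = order_best_network(ss, [1, 0]).total_score
        assert a == pytest.approx(b)


class TestOrderLocalSearch:
    def test_reaches_exact_optimum_on_worked_example(self, table2):
        res = order_local_search(table2, restarts=10, seed=3)
        assert res.total_score == pytest.approx(exact_dp(table2).total_score)

    def test_same_seed_is_deterministic(self, table2):
        a = order_local_search(table2, restarts=5, seed=7)
        b = order_local_search(table2, restarts=5, seed=7)
        assert a.total_score == b.total_score
        assert a.dag.parents == b.dag.parents

    def test_degenerate_budget_equals_seeded_order_best_network(self, table2):
        seed = 11
        res = order_local_search(table2, restarts=1, max_iters=0, seed=seed)
        order = [int(v) for v in np.random.default_rng(seed).permutation(4)]
        ref = order_best_network(table2, order)
        assert res.total_score == pytest.approx(ref.total_score)
        assert res.dag.parents == ref.dag.parents

    def test_bounded_by_exact_optimum(self, score_set_factory):
        ss = score_set_factory(n=6, max_indegree=2, N=150, seed=31)
        res = order_local_search(ss, restarts=3, seed=0)
        assert is_acyclic(res.dag)
        assert res.total_score <= exact_dp(ss).total_score + 1e-9

    def test_restarts_must_be_positive(self, table2):
        with pytest.raises(ValueError):
            order_local_search(table2, restarts=0)
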