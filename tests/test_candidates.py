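import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnprune import (
    BDeuConfig,
    NodeScoreTable,
    ScoredParentSet,
    ScoreSet,
    count_possible_cps,
    enumerate_and_score,
    forward_sample,
    legal_prune,
    percent_prune,
    random_bn,
)

from _oracles import legal_survivors


class TestCountPossibleCps:
    @pytest.mark.parametrize(
        "n,d,expected",
        [
            (100, 1, 10_000),
            (100, 2, 495_100),
            (100, 3, 16_180_000),
            (4, 3, 32),
        ],
    )
    def test_printed_totals(self, n, d, expected):
        assert count_possible_cps(n, d) == expected

    def test_matches_binomial_sum(self):
        n, d = 23, 7
        assert count_possible_cps(n, d) == n * sum(math.comb(n - 1, k) for k in range(d + 1))

    def test_exact_big_integers(self):
        # far beyond float precision; must be exact integer arithmetic
        v = count_possible_cps(500, 10)
        assert isinstance(v, int)
        assert v % 500 == 0

    def test_indegree_beyond_n_minus_one_rejected(self):
        with pytest.raises(ValueError):
            count_possible_cps(4, 4)


class TestEnumerateAndScore:
    def test_four_binary_variables_give_32_entries(self, random_dataset_factory):
        data = random_dataset_factory(n=4, N=50, seed=0)
        ss = enumerate_and_score(data, 3)
        assert ss.total_entries() == 32

    def test_indegree_zero_leaves_only_empty_sets(self, random_dataset_factory):
        data = random_dataset_factory(n=4, N=30, seed=1)
        ss = enumerate_and_score(data, 0)
        assert all(len(t) == 1 and t.entries[0].parents == () for t in ss.tables)

    def test_five_variables_indegree_two_entry_count(self, random_dataset_factory):
        data = random_dataset_factory(n=5, N=40, seed=2)
        ss = enumerate_and_score(data, 2)
        assert all(len(t) == 11 for t in ss.tables)  # C(4,0)+C(4,1)+C(4,2)

    def test_tables_sorted_canonically(self, random_dataset_factory):
        data = random_dataset_factory(n=4, N=60, seed=3)
        ss = enumerate_and_score(data, 3)
        for t in ss.tables:
            keys = [(-e.score, e.size, e.parents) for e in t.entries]
            assert keys == sorted(keys)


class TestLegalPrune:
    def test_worked_example_prunes_exactly_six(self, table2):
        legal = legal_prune(table2)
        assert legal.total_entries() == 26
        removed = {
            (i, e.parents)
            for i in range(4)
            for e in table2.tables[i].entries
            if e.parents not in legal.tables[i]
        }
        # node "1" loses {2,3},{2,4},{2,3,4}; node "2" loses {1,3},{1,4},{1,3,4}
        assert removed == {
            (0, (1, 2)), (0, (1, 3)), (0, (1, 2, 3)),
            (1, (0, 2)), (1, (0, 3)), (1, (0, 2, 3)),
        }

    def test_strictly_improving_scores_keep_everything(self):
        entries = [
            ScoredParentSet((), -10.0),
            ScoredParentSet((1,), -9.0),
            ScoredParentSet((2,), -8.5),
            ScoredParentSet((1, 2), -8.0),
        ]
        ss = ScoreSet(names=("a", "b", "c"), tables=[
            NodeScoreTable(0, entries),
            NodeScoreTable(1, [ScoredParentSet((), -1.0)]),
            NodeScoreTable(2, [ScoredParentSet((), -1.0)]),
        ])
        assert legal_prune(ss).tables[0].entries == ss.tables[0].entries

    def test_ties_are_pruned_in_favour_of_smaller_set(self):
        entries = [
            ScoredParentSet((), -5.0),
            ScoredParentSet((1,), -3.0),
            ScoredParentSet((1, 2), -3.0),  # equal score, larger set: dominated
        ]
        ss = ScoreSet(names=("a", "b", "c"), tables=[
            NodeScoreTable(0, entries),
            NodeScoreTable(1, [ScoredParentSet((), -1.0)]),
            NodeScoreTable(2, [ScoredParentSet((), -1.0)]),
        ])
        kept = [e.parents for e in legal_prune(ss).tables[0].entries]
        assert kept == [(1,), ()]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_subset_oracle(self, score_set_factory, seed):
        ss = score_set_factory(n=4, N=80, seed=seed)
        legal = legal_prune(ss)
        for i, table in enumerate(ss.tables):
            expected = legal_survivors({e.parents: e.score for e in table.entries})
            assert {e.parents for e in legal.tables[i].entries} == expected

    def test_empty_set_always_survives(self, score_set_factory):
        ss = score_set_factory(n=5, N=60, seed=42)
        assert all(() in t for t in legal_prune(ss).tables)


class TestPercentPrune:
    def test_zero_is_identity(self, table2):
        assert percent_prune(table2, 0) == table2

    def test_worked_example_node3_at_fifty_percent(self, table2):
        pruned = percent_prune(legal_prune(table2), 50)
        kept = [e.parents for e in pruned.tables[2].entries]
        # node "3": top ceil(8/2)=4 of the sorted legal list, plus the
        # force-retained empty set
        assert kept == [(0, 1, 3), (0, 1), (0, 3), (1, 3), ()]

    def test_ninety_nine_percent_keeps_top_entry_plus_empty(self, table2):
        pruned = percent_prune(legal_prune(table2), 99)
        for t in pruned.tables:
            assert len(t) <= 2
            assert () in t
            assert t.best.parents != () or len(t) == 1

    def test_out_of_range_percent_rejected(self, table2):
        for p in (-1, 100, 150):
            with pytest.raises(ValueError):
                percent_prune(table2, p)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        p1=st.floats(min_value=0, max_value=99),
        p2=st.floats(min_value=0, max_value=99),
        seed=st.integers(min_value=0, max_value=10),
    )
    def test_monotone_nesting_and_empty_retention(self, score_set_factory, p1, p2, seed):
        ss = legal_prune(score_set_factory(n=5, N=80, seed=seed))
        lo, hi = sorted((p1, p2))
        weak = percent_prune(ss, lo)
        strong = percent_prune(ss, hi)
        for t_weak, t_strong in zip(weak.tables, strong.tables):
            assert len(t_strong) >= 1
            assert () in t_strong
            kept_weak = {e.parents for e in t_weak.entries}
            for e in t_strong.entries:
                assert e.parents in kept_weak or e.parents == ()


def _legal_fraction(n, d, N, seeds):
    fracs = []
    for seed in seeds:
        bn = random_bn(n, max_indegree=min(3, n - 1), edge_prob=0.5,
                       concentration=0.3, seed=seed)
        data = forward_sample(bn, N, seed=seed + 500)
        full = enumerate_and_score(data, d, BDeuConfig())
        legal = legal_prune(full)
        fracs.append(legal.total_entries() / full.total_entries())
    return float(np.mean(fracs))


class TestLegalFractionTrends:
    """The share of legal CPSs should grow with sample size and shrink with in-degree."""

    def test_fraction_increases_with_sample_size(self):
        seeds = range(4)
        small = _legal_fraction(n=7, d=2, N=80, seeds=seeds)
        large = _legal_fraction(n=7, d=2, N=2000, seeds=seeds)
        assert large > small

    def test_fraction_decreases_with_indegree(self):
        seeds = range(4)
        shallow = _legal_fraction(n=7, d=1, N=300, seeds=seeds)
        deep = _legal_fraction(n=7, d=3, N=300, seeds=seeds)
        assert deep < shallow
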