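# bnprune

Candidate-parent-set pruning and score-based structure learning for discrete
Bayesian networks.

## The problem

A Bayesian network over discrete variables X₁,…,Xₙ factorises their joint
distribution through a directed acyclic graph G: each variable depends only
on its parents Πᵢ. Learning G from data by score maximisation is NP-hard —
the number of labeled DAGs grows super-exponentially (≈4.2×10¹⁸ already at
n = 10) — so the efficient score-based algorithms first tabulate, for every
node, the local score of each **candidate parent set** (CPS) up to a bounded
in-degree d, and then solve a combinatorial optimisation over those tables.
The tables themselves explode: 100 variables at d = 3 give 16,180,000 CPSs.

`bnprune` is a toolkit for studying how far those tables can be cut down
before the learned network degrades:

1. **Scoring.** Each (child, parent set) pair gets the BDeu log marginal
   likelihood

   BDeu(Xᵢ, Πᵢ) = Σⱼ [ln Γ(α/qᵢ) − ln Γ(α/qᵢ + Nᵢⱼ)]
                 + Σⱼₖ [ln Γ(α/(qᵢrᵢ) + Nᵢⱼₖ) − ln Γ(α/(qᵢrᵢ))],

   with rᵢ the child arity, qᵢ the number of joint parent configurations,
   Nᵢⱼₖ the data counts and α the equivalent sample size (default 1.0).
   The score is decomposable (a DAG's score is the sum of its local scores)
   and Markov-equivalent DAGs score identically.
2. **Legality pruning** (lossless). A parent set is *illegal* if some proper
   subset scores at least as high — swapping in the subset can never break
   acyclicity or lower the total, so illegal sets never occur in an optimal
   DAG and are removed exactly.
3. **Percentage pruning** (lossy). Each node's legal list is sorted by score
   and the bottom p% is dropped (the empty set is always retained so every
   DAG keeps a root node). This is the speed/accuracy dial.
4. **Search.** Exact dynamic programming over variable subsets (small n),
   a greedy constructive pass, or order-based hill-climbing with random
   restarts (large n).
5. **Evaluation.** The accuracy lost at pruning level p is the discrepancy
   **Δ = (S\* − S)/S\***, where S is the pruned-search score and S\* the
   unpruned baseline; scores are negative, so Δ ≤ 0, reported in per mille.

It is intended for researchers benchmarking structure-learning pipelines and
for anyone who needs GOBNILP-compatible score files, reproducible synthetic
ground truths, or an exact small-n learner to validate approximations against.

## Worked example

The built-in 4-node example ships the complete table of 32 scored parent
sets (sample size 5000, d = 3):

```python
import bnprune as bp

ss = bp.table2_fixture()
legal = bp.legal_prune(ss)
print("all CPSs:", ss.total_entries(), "legal:", legal.total_entries())

res = bp.exact_dp(legal)
print("optimal score:", res.total_score)
for name, ps in zip(ss.names, res.dag.parents):
    print(f"  {name} <- {[ss.names[p] for p in ps]}")

p50 = bp.percent_prune(legal, 50)
delta = bp.delta_discrepancy(res.total_score, bp.exact_dp(p50).total_score)
print("p=50 CPSs:", p50.total_entries(), "delta permille:", delta * 1000)
```

prints

```
all CPSs: 32 legal: 26
optimal score: -8783.4
  1 <- ['3', '4']
  2 <- ['3', '4']
  3 <- ['4']
  4 <- []
p=50 CPSs: 18 delta permille: 0.0
```

Legality pruning removes exactly 6 of the 32 sets; the exact optimum
(−8783.4, against −9135.5 for the empty graph) is unchanged, and here even
dropping half of each node's sorted list keeps Δ at 0 because every node's
optimal parent set survives the cut.

For a matrix of integer-coded observations there is a scikit-learn-style
estimator:

```python
from bnprune import BNStructureLearner

learner = BNStructureLearner(max_indegree=3, ess=1.0, prune_percent=0.0).fit(X)
learner.dag_.parents, learner.total_score_, learner.edges_()
```

## Command line

```sh
bnprune simulate -n 15 -d 3 --samples 5000 --seed 1 -o data.dat
bnprune score data.dat -d 3 -o scores.jkl          # legal CPSs, .jkl format
bnprune prune scores.jkl -p 90 -o pruned.jkl       # keep top 10% per node
bnprune search pruned.jkl --method dp -o net.json
bnprune curve scores.jkl --levels 0,30,60,90 --method dp
bnprune eval -n 10 -d 3                            # structure-space counts
```

Data files are whitespace-delimited text (names row, optional arity row,
integer rows); score files use the Jaakkola/GOBNILP `.jkl` dialect, so the
tables can be exchanged with GOBNILP-compatible tools in both directions.

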