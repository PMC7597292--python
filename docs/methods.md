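# Methods

## Model and scoring

We learn the structure G of a discrete Bayesian network by maximising a
decomposable score: the total score of a DAG is the sum over nodes of the
local score of the node's assigned parent set. The local score is BDeu, the
log marginal likelihood of the child's column under a symmetric Dirichlet
prior whose total mass α (the *equivalent sample size*, ESS) is spread
uniformly over the qᵢ·rᵢ cells of the conditional probability table:

    BDeu(Xᵢ, Πᵢ) = Σⱼ [lnΓ(α/qᵢ) − lnΓ(α/qᵢ + Nᵢⱼ)]
                 + Σⱼ Σₖ [lnΓ(α/(qᵢrᵢ) + Nᵢⱼₖ) − lnΓ(α/(qᵢrᵢ))]

Assumptions: complete data (no missing values), multinomial sampling,
parameter independence and modularity, and a uniform structure prior. BDeu
is score-equivalent: Markov-equivalent DAGs receive identical totals, which
the tests verify on 2- and 3-node equivalence classes.

Numerical conventions, fixed once:

- **q counts all joint parent configurations** (the product of parent
  arities), including configurations never observed. Some implementations
  use only observed configurations; the two disagree whenever a
  configuration is unobserved, and we document and test the all-configuration
  convention. Unobserved configurations contribute zero terms, so the
  implementation only visits observed ones.
- **ESS default α = 1.0** (the common default of GOBNILP-style tooling),
  exposed everywhere as a parameter. Larger α smooths the score towards
  denser graphs; the choice matters mostly at small sample sizes.
- Natural-log scale throughout; score comparisons are exact float
  comparisons with no tie tolerance. Ties are handled structurally: the
  canonical order everywhere is score descending, then fewer parents, then
  lexicographically smaller parent tuples.
- Parent configurations are indexed in mixed radix with the lowest parent
  index as the least significant digit. This is internal only; scores do not
  depend on it.

## Candidate parent sets and pruning

With n variables and maximum in-degree d there are n·Σ_{k≤d} C(n−1, k)
candidate parent sets (CPSs). Two pruning stages operate on the per-node
score tables:

- **Legality pruning** removes every parent set P of node i for which some
  proper subset Q ⊂ P has score(i, Q) ≥ score(i, P). Replacing P by Q in any
  DAG preserves acyclicity and cannot lower the total, so the rule is exact:
  the optimum over legal CPSs equals the optimum over all CPSs (tested on
  200 random instances by exhaustive search on both sides). We prune on ties
  (≥): a smaller set with an equal score dominates, which is score-safe and
  favours sparser graphs. The empty set has no proper subsets and always
  survives.
- **Percentage pruning** keeps, per node with m entries, the top
  ⌈(1 − p/100)·m⌉ entries of the sorted list (at least one). The rounding
  rule is a design choice (the cut is stated as a percentage, not a count);
  ceiling with a floor of one keeps every table non-empty. The empty parent
  set is force-retained at every level — a valid DAG needs at least one root
  node, and search must always be able to fall back to "no parents". The
  percentage applies per node, not to the global CPS pool, so every node
  keeps its locally most promising options.

The legal fraction behaves directionally as expected: it grows with sample
size (more detectable dependencies) and shrinks with maximum in-degree (more
redundant supersets); both trends are asserted on averaged synthetic
replicates.

## Search engines

All engines consume a score table set and share the canonical tie order, so
results are reproducible bit-for-bit.

- **Exact dynamic programming** (subset DP, best-sink recursion): phase 1
  computes for each node i and each subset S of the other variables the best
  table entry contained in S; phase 2 computes the best network over each
  variable subset by choosing its best sink. O(n·2ⁿ) time and memory;
  capped at n = 22, beyond which the order-based engine is suggested. The
  phase-1 sweep propagates entry *indices* in canonical order, so tie
  resolution (fewer parents, lexicographic) falls out of the index minimum.
- **Greedy constructive pass**: nodes are visited in descending order of
  potential gain (best CPS score minus empty-CPS score); each node takes the
  highest-scoring CPS that keeps the accumulated graph acyclic, falling back
  through its sorted list. The visiting order and fallback rule are our
  concrete instantiation of a constructive CPS iteration; the empty CPS
  guarantees termination. The pass is a lower bound on the optimum and is
  tested as such.
- **Order-based search**: given a node ordering, each node independently
  takes its best CPS among its predecessors (acyclic by construction); the
  exact optimum is the maximum over all orderings, which the tests exploit
  at n = 4 by full enumeration. The local search hill-climbs with
  first-improvement over adjacent transpositions from random restart orders
  — a swap of positions k, k+1 only re-decides the two swapped nodes, making
  moves cheap. This is a deliberately simple, reproducible stand-in for the
  memetic order-based algorithms used at scale; population-based operators
  are out of scope. A single integer seed drives all restarts.
- **Brute force**: exhaustive enumeration of every parent-set assignment
  with a vectorised Kahn-elimination acyclicity filter, n ≤ 5. It exists
  purely as an independent oracle for the other engines.

## The pruning experiment

`pruning_curve` scores once, legality-prunes, then for each level p
percentage-prunes and re-learns with the same engine and seed. Level 0 is
always included and defines the baseline S\*. The discrepancy is

    Δ = (S* − S)/S*

reported in per mille. With negative scores and S ≤ S\*, Δ ≤ 0; exact search
over nested feasible sets makes Δ monotone non-increasing in p, which is
asserted. Δ is invariant to positive rescaling of both scores. Wall-clock
time per level is recorded for information only and never tested (it is
hardware-dependent).

The shipped experiment scale — 15 nodes, d = 3, N = 5000 observations,
levels {0, 30, 60, 90} — exercises roughly 7000 scored CPSs and a 2¹⁵-subset
DP per level in seconds while showing the qualitative regime of interest:
Δ = 0 at low pruning, slow degradation in the mid range, visible loss at
aggressive pruning.

## Structure-space counts

The number of labeled DAGs uses the standard inclusion–exclusion recurrence

    a(m) = Σ_{i=1..m} (−1)^{i+1} C(m, i) 2^{i(m−i)} a(m−i),  a(0) = 1,

in exact integer arithmetic, validated against exhaustive enumeration of all
2^{n(n−1)} digraphs for n ≤ 5 (1, 3, 25, 543, 29281 — the oracle recounts
these at test time). The number of structures consistent with node orderings
is 2^{n(n−1)/2}, the count of subsets of a fixed linear order's possible
edges. At n = 10 these are ≈4.2×10¹⁸ and ≈3.5×10¹³ — the gap that motivates
order-based search.

## Synthetic data generator

The generator emulates the standard benchmark recipe: a random DAG (uniform
node order, independent edge inclusion with probability `edge_prob`,
per-node in-degree capped at d by keeping the most recent predecessors),
conditional probability tables drawn row-wise from a symmetric
Dirichlet(`concentration`), and data by ancestral sampling. Defaults:
arity 2, edge_prob 0.3, concentration 0.5 — small enough to give skewed,
informative conditionals from which structure is learnable at moderate N,
the regime the pruning experiments need. All routines are deterministic in
a single integer seed.

What the generator does **not** emulate: the handcrafted, highly structured
CPTs of the published benchmark networks; non-uniform arities within a
network (supported but not defaulted); missing data; deterministic or
context-specific dependencies. Passing tests on this generator therefore
demonstrate correctness of the machinery and the qualitative pruning
behaviour, not performance claims about any particular real-world network.

Raw Dirichlet draws can produce degenerate rows (probabilities at 0/1) or
near-identical rows, making the generating DAG unfaithful — some true edges
are then invisible at any sample size. The structure-recovery smoke test
therefore rejection-samples its ground truths: probabilities clipped to
[0.1, 0.9] and every pair of CPT rows at least 0.25 apart in total
variation. Under those conditions (6 nodes, d = 2, N = 10,000) exact search
recovers the true Markov equivalence class in at least 8 of 10 seeded
replicates. Without the faithfulness guarantee the rate is much lower — a
property of the statistical problem, not of the implementation.

The 4-node worked example is embedded as a score-level fixture (32 entries
to one decimal place). Its generating network is not available, so the
fixture is used as an input to pruning and search, never re-derived from
data.

## File formats

Data files: whitespace-delimited text, a header of unique names, an optional
arity row, integer rows. Arity-row detection is heuristic by necessity: the
second row is taken as arities iff every token is an integer ≥ 2 strictly
exceeding every later value in its column; files written by the package
always include the arity row, making round-trips exact. Score files follow
the Jaakkola/GOBNILP `.jkl` dialect; parent fields may be names or 0-based
indices (auto-detected: all-integer tokens matching no declared name are
indices), parsing is order-insensitive, and scores are written with six
decimal places, which bounds round-trip error at 5×10⁻⁷.

## Known limitations

- Exact DP is memory-bound (n ≤ 22); no A*, ILP or branch-and-bound engines.
- BDeu with small α at large N occasionally prefers a spurious weak edge;
  this is a known property of the score, visible in the recovery test's
  failure mode, not corrected for here.
- Only BDeu is implemented; no BIC/AIC/qNML alternatives.
- No additional score-bound pruning rules beyond subset-score legality; the
  percentage rule is deliberately the only lossy mechanism so its effect can
  be measured in isolation.
- The wall-clock "time to best" in curve records depends on the host and is
  informational only.
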