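# Methods

`logicnet` analyzes qualitative models of gene regulation: a signed
directed network (activation / inhibition edges, optional AND
connectors) is translated into a synchronous Boolean model, whose
long-term behaviour is then summarized three ways — structurally
(signed feedback loops), dynamically (the exact set of stable states
and expression-rate statistics over it) and causally (which genes a
single knockout or overexpression forces to a constant).  This note
records the models, conventions, numerical choices and their limits.

## From a signed network to a Boolean model

Each node carries one update rule over {0,1}; the synchronous map
updates all nodes from the same input state.  Explicit rule files
always take precedence.  When rules are derived from a network the
default *inhibitor-dominant* convention is used:

    f_target = (OR over activator terms) AND (AND over NOT inhibitor terms)

* Edges sharing an AND-group tag on the same target form one
  conjunctive term (all members must be ON).  We apply the same
  grouping to inhibitor edges — a grouped inhibitor term blocks only
  when all its members are ON — because the gating semantics of an AND
  connector do not depend on the edge sign.
* A node with only activators omits the inhibitor clause; a node with
  only inhibitors is ON exactly when no inhibitor term fires.
* A node with no regulators (a network input) gets the identity rule
  `f = x`, so it is a free variable in every stable state.  This is the
  only convention under which a curated map with many inputs yields
  families of stable states indexed by input combinations, which is the
  behaviour such models display.

This convention is the de-facto standard for literature-curated
logical models; it is a modelling choice, and several Boolean models
fit any given signed network.  Rule files exist precisely so that a
differently-calibrated model can be supplied.

Expression trees are simplified by a fixed local pass only: constant
folding, flattening, duplicate removal, double negation, and
literal-complement cancellation (`x & !x -> 0`, `x | !x -> 1`).  No
full two-level minimization is attempted — soundness matters here,
minimality does not.  The canonical on-disk form of a rule is the full
disjunctive normal form over the *essential* support (variables the
truth table actually depends on), so two semantically equal models
serialize byte-identically; beyond 10 essential variables the writer
falls back to a deterministic syntactic normal form.

## Feedback loops

A feedback loop is a simple directed cycle, counted once up to
rotation (canonical start: lexicographically smallest node) and once
per choice among parallel edges of different sign; its sign is the
product of its edge signs, i.e. negative exactly when the number of
inhibitions on it is odd.  Self-loops are length-1 cycles signed by
their single edge; a census view without them is provided, since
whether published counts include self-loops is often unstated.
Node-level cycles come from `networkx.simple_cycles`; the census is
guarded by a loop cap (default 10^6) and an optional length bound for
dense networks, and is checked in the tests against an independent
depth-first enumeration.

## Exact stable-state detection

A state is stable iff it satisfies every *consistency equation*
`f_i(x) = x_i`.  The solver:

1. builds one equation per node (tautological equations — free inputs —
   are dropped; a contradictory one, e.g. `x = !x`, empties the answer);
2. greedily merges equations that share variables into blocks whose
   joint support stays within a budget (default 25 variables), ties
   broken by node order;
3. solves each block by chained hash-joins of the equations' satisfying
   assignment tables (only solutions are ever materialized, never the
   2^|support| product);
4. joins block tables pairwise, smallest first, preferring pairs that
   share variables; variable-disjoint tables meet in a cross product
   last;
5. returns the result as disjoint *cubes* — a pinned partial assignment
   plus a set of free variables covering 2^|free| states each.  After
   every join, rows differing in exactly one pinned position are merged
   and that position freed, iterated to a fixed point, which is what
   keeps input-rich solution sets down to a handful of cubes.

Cardinality is the sum of cube sizes and never requires expansion.
Joins are capped (default 2·10^6 rows) and fail with an explicit
resource error rather than exhausting memory: worst-case solution sets
are genuinely exponential, and no join order avoids that.  Per-node
rule supports beyond 19 regulators are refused (the satisfying table
itself would be unenumerable).  Everything is keyed to the model's node
order, so results are deterministic; cardinality is invariant to node
reordering and to the budget (tested).

A guarded brute-force enumerator (n ≤ 22) is the independent oracle;
the suite asserts exact set equality on hundreds of random models, and
that every solution is fixed under asynchronous (single-node) updates
too — the stable-state set is update-scheme independent.

Uniform sampling without replacement draws global state indices and
maps them through the cube list; expansion enumerates cubes in order
and Gray-codes the free variables, so both are reproducible.

## Statistics over the stable states

The exact rate at which a node equals 1 over the whole set is
cube-analytic: a pinned node contributes `value * 2^|free|`, a free node
`2^(|free|-1)`.  Nodes with rate strictly between 0 and 1 are the
*non-constant* set.

Clustering operates on an explicit state matrix: the full expansion
when the set has at most 2^21 states, otherwise a seeded uniform sample
of that size (full-set k-means over tens of millions of rows buys no
statistical precision worth the memory).  Columns are standardized to
mean 0 / sd 1 (constant columns dropped with a log message), clustered
by Lloyd k-means with k-means++ seeding, Euclidean distance, best of 10
restarts (k = 4 by default, exposed), and the clusters are merged into
two groups by complete-linkage agglomeration of the centroids.  Group 1
is the group with the higher rate of a supplied marker gene, else the
smaller-mass group — the orientation is always reported explicitly.
Per-node cluster/group rates, the group difference, and the group
ratio (infinite when the denominator group's rate is 0 — flagged, not
an error) are tabulated; a gene is *selected* when |difference| > 0.5
or the ratio leaves [0.8, 1.2].

Model-vs-annotation consistency calls a gene consistent when its
overall rate is on the expected side of 0.5; a rate of exactly 0.5 is
inconclusive and excluded from the denominator, as are unknown levels
and genes absent from the model.

## Control effects

Clamping node k to v replaces its rule by the constant and folds the
constant through every other rule; iterating until no new rule folds to
a constant yields the forced sets A(k,0), A(k,1) (clamp 0) and B(k,0),
B(k,1) (clamp 1).  The iteration is monotone and terminates within n
sweeps.  Propagation is *sound but deliberately incomplete*: it reports
only guaranteed constants; rules that merely shrink are partial effects,
tallied in a side count and excluded from the matrix.  The per-pair
code is 3 (co-expressed: A0 and B1), −3 (opposite), ±2 (only the ON
clamp forces), ±1 (only the OFF clamp forces), 5 (same constant under
both clamps — direction unclear; realized this way as the one
contradiction-flavoured outcome the code table leaves), 0 otherwise.
Soundness is tested against brute-force fixed points of the clamped
models.

### Expression-based validation

Predictions are checked against a sample × gene matrix: samples are
split at the controlling gene's median (ties to "low"); each signed
predicted pair must show a log2 fold change of matching sign, passing a
Welch t-test at alpha = 0.05 (no multiple-testing correction) *and* a
fold-change floor of |logFC| ≥ 1 (two-fold, the conventional "obvious
change").  The floor exists because genes that are constant across the
stable states produce noise-only splits; roughly alpha of them reach
significance with near-zero fold changes and random sign, which would
contaminate the rate with pairs that carry no information.  The
permuted-label null check in the tests disables the floor
(`min_abs_logfc = 0`) because it is a pure sign experiment.  A
multi-dataset mode counts a pair consistent when at least two datasets
conform.

## Synthetic data

* Random networks: `mean_in_degree` is the network-wide mean, so the
  expected edge count is `n_nodes * mean_in_degree`; the default shape
  (91 nodes, mean in-degree 2 → ~182 edges, 20 regulator-free inputs,
  30% inhibition, 10% AND-connector frequency) mimics a curated cancer
  signalling map.  Regulated nodes draw `1 + Poisson(lam)` distinct
  regulators so none is orphaned.
* Planted clusters: k random binary centroids plus independent bit
  flips, ground-truth labels returned; at 5% flips and the default
  sizes, k-means recovery is essentially exact (ARI ≥ 0.99, tested).
* Expression matrices: stable states mapped {0 → mu0 = 2, 1 → mu1 = 8}
  plus N(0, sigma = 0.6) noise — sigma is 10% of the level separation.
  The two-level Gaussian is the simplest auditable choice: the
  validation procedure consumes only the sign and significance of fold
  changes, so any location-scale family would do.

What the generators do *not* emulate: probe structure, normalization
artefacts, batch effects, correlated noise, or the biased topology of a
hand-curated network (motif enrichment, hubs with coherent signs).
Passing tests therefore demonstrate the correctness of the algorithms
and the internal consistency of the pipeline, not biological fidelity
on real curated networks.

## Problem sizes and reproduction

`scripts/acceptance.py` re-runs every stage from scratch at fixed
sizes chosen to exercise the full pipeline comfortably on one CPU: the
topology census on the default 91-node shape; exact stable-state
enumeration, clustering, control effects and expression validation on a
40-node / 10-input draw (random dense networks can have genuinely
exponential solution sets, which the solver's row cap converts into an
explicit error; the 40-node scale enumerates exactly and fast at any
seed); solver-vs-oracle agreement on 50 models with n ≤ 12; and
planted-cluster recovery at 2000 × 60.  All randomness derives from
`--seed`.

## Known limitations

* Stable states only: cyclic attractors of the synchronous map are out
  of scope, and clamp propagation says nothing about oscillatory
  responses.
* The solver's worst case is exponential; the row cap makes the failure
  mode explicit rather than fixing it.
* k-means row-order invariance holds as a partition for well-separated
  data (asserted via ARI), not as a bitwise guarantee of the label
  vector.
* The inhibitor-dominant convention is one of several defensible
  translations of a signed network; conclusions drawn from
  convention-built models inherit that choice.
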