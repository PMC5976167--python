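# Methods

This note records the modelling choices behind `triadnet`: what each
component assumes, which parameters matter, and where genuinely open
design questions were settled by the package.

## Networks and the triad census

Networks are directed, binary and loop-free on `n` labelled units, stored
as dense adjacency matrices (the study sizes, a few dozen units, make
dense storage the clear choice).  The triad census counts the 16
Holland–Leinhardt classes over all C(n,3) unit triples.  Labels follow
the statnet/`sna` orientation convention — `021D` is one sender to two
receivers (`A←B→C`), `021U` two senders to one receiver, `111D` is
`A↔B←C`, `111U` is `A↔B→C`, `120D`/`120U`/`120C` analogously, `030T` the
transitive triple and `030C` the 3-cycle.  All classification flows
through one 64-entry lookup table built from canonical representatives at
import time; the unit tests verify every entry against
`networkx.triadic_census` and check the arc-reversal duality
(U↔D labels swap, everything else fixed).

Census updates inside the generators are incremental: toggling arc
(i, j) only affects the n−2 triples containing both endpoints, giving an
O(n) delta that a standing test keeps equal to the full recount.

### Paths of length three

The three-paths statistic is the number of directed three-arc *trails*:
ordered arc triples (a→b, b→c, c→d) with distinct arcs but repeatable
units, computed as `sum(A³) − 2·(mutual dyads)`.  The trail reading is
chosen because the cluster-level pattern the statistic is meant to
suppress (e.g. 1 → 2 → 3 → 2) revisits a cluster, and because it is the
common edge-based ERGM statistic; a strict-path variant (four distinct
units) is available via `distinct_units=True` for sensitivity checks.

## Blockmodels, level of errors, randomization

Seven pre-specified types are built from canonical K×K images
(structural equivalence: only null and complete blocks).  Conventions
settled here: cluster 1 is the core (core–periphery) or the top level
(hierarchy/transitivity); lower clusters send arcs upward, hierarchies
only to the adjacent level; transposing the image flips the direction
convention.  Default sizes for n = 24: (8, 8, 8) for three-cluster types
and (8, 16) core/periphery.  The sizes are a documented assumption — the
published A-measure table is analytically consistent with the (8, 8, 8)
hierarchy defaults but implies other, unpublished sizes for the
core–periphery types (the asymmetric column matches 12/12 in closed
form).  All sizes are configurable; results quoted in the acceptance
pipeline state theirs explicitly.

The level-of-errors perturbation relocates
`k = round(LE·(m − m²/(n²−n)))` arcs (half-up rounding) from uniformly
chosen complete-block positions to uniformly chosen empty null-block
positions.  Two invariants pin the formula's reading: k = 0 at LE = 0,
and at LE = 1 the complete- and null-block densities coincide.  Each
relocation costs exactly 2 criterion errors under the true partition,
which the tests exploit.  "Totally randomized" means a uniform digraph
with exactly m arcs (density matched per draw, not in expectation).

## Triad profiles

Allowed/forbidden classification is computed exactly from the ideal
census rather than from Monte-Carlo A-measures, so set membership carries
no sampling noise.  The A-measure (ideal count / mean randomized count;
default 10 000 randomizations) is reported for interpretation and
cross-checked against closed-form expectations where available
(hypergeometric moments of the fixed-m uniform digraph).

Selected subsets: the selected *allowed* sets equal the allowed sets
minus 021C for the hierarchical-null-diagonal type and minus 300 for the
transitivity-complete-diagonal type — in both cases the dropped type's
A-measure is near 1, i.e. its count is explained by density alone.
Which *forbidden* types belong to a reduced selected set is not
derivable from first principles here, so `selected_forbidden` is
configuration-supplied and defaults to the full forbidden set (a logged
warning notes the substitution).  This default makes "selected"
equivalent to "selected allowed + all forbidden".

## The RL generator

Algorithm: from a uniform random digraph with the ideal arc count, M
iterations each propose dissolving one uniform arc and establishing one
uniform non-arc, accepting iff the tracked statistic vector gets strictly
closer (squared distance) to the ideal target.  Two conventions are fixed
deliberately:

* the closeness ratio is oriented with the *current* distance in the
  numerator, so CR > 1 literally means "the proposal is closer";
* ties (CR = 1) are rejected, making the distance trace strictly
  decreasing over accepted moves and the descent terminating.  Accepting
  ties was tried and measurably changes nothing at the default budgets.

Default M = 6000.  The accept rule is greedy, so the chain can lodge in
local optima; restart or annealing schemes are intentionally out of
scope.  A practical observation recorded here for users: at M = 6000 the
cells differ strongly in convergence (the asymmetric core–periphery and
transitivity targets are nearly realized, the cohesive and symmetric
core–periphery targets are not), and MIVs keep rising well past this
budget for some cells while the hierarchical-null-diagonal cell plateaus
low regardless — the local-structure set, not the budget, is its binding
constraint.

## The ERGM generator

Fixed-coefficient Metropolis–Hastings: +2/−2 for allowed/forbidden
statistics (coefficient estimation is out of scope; the package's
purpose is generation, not inference).  Proposals are symmetric — free
mode toggles one uniform ordered pair, fixed mode swaps a uniform arc
with a uniform non-arc — so acceptance is `min(1, exp(θ·Δg))` with no
Hastings correction.  Chains start from a randomized ideal network
(density matched, structure destroyed), which keeps the free chain from
the empty/complete absorbing regions that plain random starts invite.
Burn-in defaults to 0: the reported object is the state after the
iteration budget (default 10 000), not a stationary draw.  A dedicated
exhaustive test on 4 units verifies the chain's stationary law against
the enumerated exponential-family distribution (χ² over all 4096
digraphs).

Free-density runs need an `edges` coefficient; `tune_edges` bisects it
until the mean density of 30 generated networks is within ±0.05 of the
ideal density.  The search brackets the root first and expands the
initial bracket [−10, 10] geometrically (to at most ±100) when the root
lies outside.  The expansion matters in practice: with the three-paths
penalty in the model, every arc addition from a sparse state is crushed
by forbidden-statistic deltas until θ_edges ≈ 35, so the default bracket
alone cannot reach the target density.

The hierarchical fix model adds the three-arc-trail count at −2 and
raises one 021-chain coefficient to +4.  The boosted label defaults to
021C (the chain the ideal three-level hierarchy is made of) and is
configurable to 021D, since both orientations are defensible and the
choice visibly affects the number of recovered levels.

## Blockmodeling fit and the MIV

The criterion counts arcs in null blocks plus missing arcs in complete
blocks for a fixed image.  The search is steepest-descent local search
over single-unit moves and pairwise exchanges (moves that would empty a
cluster are disallowed), 100 random restarts, random tie-breaking from
the run's seed.  Neighborhoods are evaluated through rank-one updates of
the cluster-pair arc-count matrix `B = ZᵀAZ`, vectorized per cluster
pair, so a full fit costs well under a second at n = 24.  An exhaustive
oracle (all 2⁸ assignments at n = 8) confirms the restarted search
attains the global minimum.

MIV = 1 − mean(P_m/P_r) over generated/randomized pairs.  One
randomization per generated network (a deliberate variance source kept
for comparability); a pair whose randomization fits perfectly (only
possible for tiny networks) is redrawn up to 5 times then dropped with a
warning.

## Problem sizes and tolerances

The package's replication pipeline (`scripts/acceptance.py`, and the
acceptance tests) uses 10 generated networks per cell with RL M = 6000,
ERGM 10 000 iterations and 100 fit restarts on 24-unit networks — a
fifth of the full 50-network design, chosen so the whole pipeline reruns
from scratch in minutes while keeping cell-level Monte-Carlo error a few
percentage points.  Stochastic cell values are asserted within ±10
percentage points (±5 for the near-saturated asymmetric core–periphery
cell); exact limit cases (ideal-input MIV = 1) are asserted exactly.

## Known limitations

* The RL accept rule is greedy; some cells are far from converged at the
  default budget and their MIVs are correspondingly conservative
  (see the RL section above).
* Equal default cluster sizes are an assumption, not a reproduction of
  the original study's (unpublished) sizes; A-measure magnitudes and the
  harder cells' MIVs are sensitive to them.
* Reduced selected-forbidden sets are user configuration, not derived.
* Only structural equivalence (null/complete blocks) is supported; no
  regular-equivalence block types, no valued or undirected networks, and
  no coefficient estimation for the ERGM.
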