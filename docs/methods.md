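# Methods

## Data model

A character matrix is a rectangular grid of taxa × characters.  Every
cell carries a set of states plus a kind flag: *observed* (singleton),
*polymorphic* (an observed multi-state cell, e.g. the single `$` = {0,1}
cell of the reference matrix), *missing* (`?`) or *inapplicable* (`N`).
All characters are unordered (Fitch) with unit weight; a character's
observed-state set is defined by its column, not by any external state
list, so a state described but never scored does not exist for the
analysis.

Missing and inapplicable cells are both resolved to the character's full
observed-state set for every optimization purpose.  This wildcard
treatment matches standard parsimony programs; no inapplicable-aware
algorithm is used, and the two kinds are kept distinct only for census
and reporting.  Polymorphic terminals enter the Fitch pass as their
state set (union semantics); an alternative reading in which a
polymorphic terminal must truly exhibit each of its states is available
behind the `polymorphic_fixed` flag of `min_steps`/`max_steps` but is
not the default, and with the reference matrix's single polymorphic cell
the choice is immaterial to the reported indices.

The packaged reference matrix is a cell-for-cell transcription of the
printed data table (20 taxa, 38 characters, one polymorphic cell, four
missing, four inapplicable), guarded by a sha256 committed with it.

## Scoring

Resolved trees are scored with the classic Fitch downpass over uint8
bitmasks (contract: up to 8 states; the data use 3), one mask per
character, rooted arbitrarily — length is invariant under rooting.  The
kernel is numba-compiled with a pure-Python fallback and supports an
early-exit bound for the search inner loop.

All per-branch and polytomy-aware quantities use an exact unit-cost
dynamic program over states (Sankoff-style): a downpass gives D[v][s],
the optimal cost of the subtree of v given state s; an outside pass
gives Out[v][s], the optimal cost of everything above, excluding the
branch to v.  A branch is *forced* to change for a character when
minₛ(D[v][s] + Out[v][s]) exceeds the character's length; the branch's
minimum length is the count of forced characters.  The DP agrees with
the downpass on resolved trees and generalizes it to multifurcations
(Hartigan's observation), which is how consensus trees are scored.

Per-character bounds:

* mᵢ — minimum conceivable steps on any tree: the minimum number of
  states that intersect every non-empty cell set (exact exhaustive set
  cover over ≤ 8 states), minus one.  With wildcard cells this equals
  the minimum over all cell resolutions of (#distinct states − 1).
* gᵢ — maximum conceivable steps: the exact length of the completely
  unresolved star tree, n − maxₛ |{cells containing s}| over non-empty
  cells; ambiguous cells thereby take their best covering state.  This
  dominates the Fitch length of every resolved tree.

Both bounds are verified in the tests against brute-force oracles
(enumeration of internal labelings, all topologies at small n, and the
star-tree minimization over assignments).

## Tree search

*Branch and bound* (exact, default ceiling 14 taxa): stepwise addition
in fixed taxon order, pruning when the partial length plus a lower-bound
increment (states required by unplaced taxa but absent from all placed
or unplaced cells) exceeds the incumbent, which is initialized by greedy
addition.  Ties with the incumbent are never pruned, so the full optimal
set is returned.

*Heuristic search* (default protocol: 100 random-addition replicates,
TBR, hold ≤ 10,000 trees, seed 42): each replicate builds a tree by
greedy stepwise addition in a random taxon order (first-found among
equal-best insertion edges, in a deterministic edge order) and descends
by first-improvement branch swapping to a local optimum.  The
best-length replicate trees then seed an island closure: equal-length
TBR (or the configured swap) neighbors are explored exhaustively until
no new topology of the best length is reachable, restarting if a better
tree is encountered.  The defaults are sized so that recovering a small
island of optima on a ~20-taxon matrix is essentially certain while a
full run stays in the tens of seconds on one CPU.

TBR is implemented as all bisections × all reconnection-edge pairs (the
pair recreating the original tree is skipped); SPR restricts one side to
its original attachment point; NNI swaps subtrees across internal
edges.  All enumeration orders are deterministic given the replicate
seed, and replaying a `SearchConfig` reproduces the identical
`SearchResult`, byte for byte in the JSON report.

MPT counting depends on the collapsing rule, so the rule is fixed and
stated: an internal branch is contracted when its minimum length over
all optimal reconstructions is zero ("min-length-zero"), and topologies
are then deduplicated by bipartition set.  Both the resolved and the
collapsed counts are always reported, since published tree counts do not
always state their rule.

## Consensus and indices

The strict consensus contains exactly the bipartitions common to all
input trees (verified against brute-force intersection and against
dendropy's consensus).  Ensemble indices are computed on a resolved MPT,
not on the polytomous consensus — Fitch length on a polytomy is
well-defined here via the DP, but the conventional published CI/RI
accompany the MPTs, and every MPT shares Σs = L, so the ensemble ratios
are identical across the optimal set.  Two display conventions are
always computed: over all characters and over parsimony-informative
characters only (a character is informative when ≥ 2 states each occur
in ≥ 2 single-state cells).  Comparisons against two-decimal published
values use round-half-up.

A provable aside the dual report makes visible: excluding uninformative
characters changes CI but can never change RI, because every
uninformative character has m = s = g on any tree and so contributes
zero to both RI sums.

## Synapomorphy mapping

Reports are polarized by rooting on the pendant edge of the most distant
sampled outgroup (*Spaethiella* sp. for the reference data); rooting
never changes lengths, only change directions.  ACCTRAN and DELTRAN are
realized as greedy preorder assignments constrained to the optimal set
at every step (choices minimize D[v][s] + [s ≠ parent state]), with the
tie broken toward a change for ACCTRAN and against one for DELTRAN, then
toward the smallest state; both therefore sum exactly to the
character's length, on multifurcating trees too, where changes are
attributed only to resolved branches.  A change is *unambiguous* when
both reconstructions place it on the same branch with the same states.
Clade support lists the stem-branch changes of a named terminal set in
all three classes; when the consensus lacks a group, the reproduction
report maps its support on the best tree containing it and flags the
absence rather than asserting the published statement.

## Synthetic data

The generator emulates the reference matrix's shape: 20 taxa, 38
characters, about a third 3-state, ambiguity at the observed sparsity
(p_missing = p_inapplicable = 0.005, p_polymorphic = 0.0015 — a few
cells per matrix), on a uniformly sampled unrooted topology.  The
default change model places an explicit number of state origins per
character on distinct branches (mixture 1:55%, 2:30%, 3:15%, averaging
1.6 — mild homoplasy of the same order as the reference data's CI),
painting the subtree below each origin with a new state, so homoplasy is
exactly controlled and the realized change count on the true tree is
tracked per character; a k-state Markov jump model (`mk`, expected
events per branch = 0.15 by default) is provided for rate-based realism.
Ambiguity is injected after evolution and can only blur signal; the true
tree's Fitch length therefore never exceeds the tracked origin count,
and with no ambiguity and single origins it equals the character count
exactly — the surfaces the recovery tests assert.

What the generator does not emulate: correlated characters, ordered or
weighted characters, asymmetric state frequencies, and
inapplicability that follows character hierarchies (its `N` cells are
random).  Passing recovery tests on clean simulations shows the
search/consensus machinery is correct, not that real morphological data
of this size always yield the true tree.

## Reproduction of the reference analysis, and known tensions

On the packaged transcription the pipeline reproduces the published best
length exactly (83 steps; the heuristic's optimum is confirmed by an
independent implementation and is provably global, since the matrix
minus its polymorphic character admits 81 steps and that character needs
two) and the published CI (Σm = 49, 49/83 = 0.59, all-characters
convention).  Three published values do not reproduce from this
transcription, and the report states them rather than adjusting them:

* RI computes to (211 − 83)/(211 − 49) = 0.79 under both conventions
  (convention-invariance proven above), one point above the published
  0.78.
* The optimal set is six resolved MPTs — three of them mere permutations
  of three outgroup terminals with identical rows — collapsing to two
  topologies; the published count of four lies between the two reported
  counts.
* No optimal tree contains the nine-species *Stoiba* clade of the
  published consensus figure (the *Chelymorpha*/*Phytodectoidea*/
  *Stolas*/*Elytrogona* block attaches inside the *Stoiba* grade), so
  the strict consensus lacks the *Stoiba*, Cuban and Jamaican groups;
  the brachypterous five-species clade is recovered, with the
  wing-reduction character (29) as its unambiguous stem synapomorphy,
  and the Jamaican pair is supported by character 5 on the trees that
  contain it, as published.

The likeliest cause is small differences between the matrix as printed
and as analyzed; the package deliberately ships the printed table
verbatim, integrity-checked, and reports what it implies.

## Numerical and engineering notes

Problem sizes in the default test run are chosen to keep brute-force
oracles exact: ≤ 7 taxa for labeling enumeration (≤ 945 topologies),
≤ 10 for heuristic-vs-exact comparisons.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; no output
ordering depends on Python set/hash iteration (trees serialize through a
canonical newick: children ordered by smallest descendant label, spaces
as underscores).  Degenerate inputs are errors, not guesses: matrices
need ≥ 1 taxon and character, trees ≥ 3 leaves, heuristic search ≥ 4
taxa, exact search refuses > 14 taxa by default, and unrooted trees are
rejected where polarity matters.
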