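# Methods

## Model and standing assumptions

A system is `N` binary units with discrete synchronous updates.  Its
dynamics are given state-by-node: for every previous state `s` (indexed
little-endian, unit 0 = least significant bit) and unit `i`, the
probability that `i` is ON at the next step.  The joint transition
probability is the product of these per-unit conditionals — conditional
independence of the units given the full previous state.  This is not a
restriction the code merely tolerates: both causal marginalization and
the φ measure are defined in terms of it, and state-by-state input files
are rejected unless they factorize this way (tolerance 1e-9, the
offending row named).  There is no instantaneous causation and no
non-Markovian memory; units are strictly binary.

## The φ calculus

*Effect side.*  The single-unit effect repertoire of a mechanism `m` is
the uniform average of the unit's ON-probability over the `2^|W|` states
of the units outside the mechanism (`W = S − M`); a multi-unit purview is
the product of its single-unit repertoires.  This per-unit-then-product
order is deliberate and is never replaced by marginalizing the joint: the
product removes residual correlations that marginalized units with
divergent connections would otherwise leave behind.  The maximal effect
state maximizes `πe(z|m)·log₂(πe(z|m)/πe(z;M))`, where the unconstrained
repertoire `πe(z;M)` is the uniform average of the *joint* repertoires
over all mechanism states (not a product of per-unit averages — the two
differ, and the average-of-joints form is the defining one).  φ is then
selectivity × positive-part log-ratio against the partitioned repertoire
at the MIP.

*Partitions.*  `Θ(M,Z)` is every division of the mechanism and purview
units into at least two parts `(M_i, Z_i)`; a part may be one-sided but
not empty, and the identity is excluded.  Equivalently: all set
partitions of the disjoint slot union `M ⊔ Z` into ≥ 2 blocks.  This
family makes the 1×1 pair have exactly one partition (the complete cut)
and admits parts such as `(M, Z₁)|(∅, Z₂)`.  A `bipartitions` scheme
(two-part subset) is provided for ablation.  `N(θ) = |M||Z| − Σ|M_i||Z_i|`
counts severed mechanism→purview connections; every valid partition
severs at least one.

The MIP search does not enumerate partitions literally.  Both the
partitioned repertoire and `N(θ)` depend only on the map sending each
purview unit to the mechanism subset it remains connected to, so the
search enumerates one representative per such map (pairwise-disjoint
retained subsets).  The reduction is exact, and the test suite checks it
against explicit partition enumeration on small pairs.  It is also what
makes the `Σφe` sweeps feasible: a 6×6 pair has ~4.2 million partitions
but ~1.4 million maps, each evaluated in a handful of cached lookups.

*Normalization.*  Eq-style normalization by `N(θ)` is used **only** to
select the MIP; the reported φ is the un-normalized loss at the selected
partition.  The two are deliberately kept distinct in the code.

*Cause side.*  The cause repertoire multiplies, over mechanism units, the
likelihood of that unit's state given each purview state (non-purview
inputs at t−1 uniformly averaged), then normalizes over purview states.
A mechanism state reachable from no purview state yields a flagged
undefined repertoire and φc = 0.  The unconstrained cause repertoire
mirrors the effect side: the average of cause repertoires over mechanism
states, restricted to states whose repertoire is defined.  Partitioned
cause repertoires multiply per-part *normalized* cause repertoires; a
part whose likelihood normalizer vanishes (possible only in contrived
deterministic cases) falls back to the uniform distribution over its
purview — a maximum-entropy convention, recorded here because no
principled value exists.

*Tie-breaks* (all deterministic, all flagged on results):

* maximal state: lexicographically smallest purview state, little-endian;
* MIP: among partitions whose normalized loss ties within 1e-9, the one
  severing the most connections wins, then canonical enumeration order.
  The largest-cut rule is what lets the all-AND system report φe = N²
  rather than the equally-normalized but smaller unit-aligned loss;
* purview search: strictly larger φ wins; at ties the earlier candidate
  in the order "larger purview first, then lexicographic" is kept.

Float comparisons use 1e-9 throughout; repertoires must sum to 1 within
1e-9.

## Constructed families

`threshold_system(N, K)` is the high-selectivity family: a unit is ON at
t+1 iff its own bit is ON **and** at least `K` units in total are ON.
The constraint part (entries forced to 1) is exactly what "every size-K
mechanism specifies itself with probability 1 in the all-ON state"
requires; every unconstrained entry is set to 0, which minimizes the
partitioned repertoires and hence maximizes the achievable φe.  The
family interpolates between the copy system (`K = 1`, every single-unit
mechanism reaches φe = 1) and N-input AND gates (`K = N`, the full
mechanism reaches φe = N²).  The defining selectivity property is
re-verified computationally at construction time, so any change to the
family breaks loudly rather than silently.  The evaluation state defaults
to all-ON — the state the construction is optimized for — and is
configurable; a scan over all `2^N` states at several (N, K) confirms
all-ON maximizes the reflexive `Σφe`.

`random_deterministic(N, seed)` draws a single density `q ~ U(0,1)` per
run and fills the unit tables with 1s at that density; `random_stochastic`
draws every entry from `U(0,1)`.  `hamming74_system()` maps each of the
128 seven-unit states to its nearest (7,4) Hamming codeword (a perfect
code, so the map is total and deterministic).  Seeds, family and draw
order are recorded in sweep manifests; identical configuration yields
byte-identical CSV output.

These generators emulate the *structural* conditions studied — perfect
self-specification, unstructured determinism, unstructured noise,
error-correcting attractors.  They do not emulate biological realism in
any other sense: no spatial structure, no heterogeneous in-degrees, no
correlated noise.  Passing tests therefore demonstrate properties of the
calculus and of these idealized families, not claims about real neural
substrates.

## Bounds

`eq6_sum_bound` (`N²·2^N/2`), `eq7_sum_bound` (`N(N+1)·2^N/4`) and
`system_phi_s_bound` (`N(N−1)`) are exact integer/rational evaluations,
cross-checked against explicit subset sums.  The reduced candidate family
for a reflexive size-K pair of the threshold construction contains the
complete cut plus the aligned bipartitions by part size — `⌊K/2⌋+1`
candidates (the wording "K2+1" is read as `⌊K/2⌋+1`; reading it as K²+1
would still be *more than* exponential savings but contradicts the stated
linear complexity, and the exhaustive-search equivalence test on N ≤ 5
settles the question empirically).  `numerical_sum_bound(N)` composes
`C(N,K)·φe*(N,K)`; an independent closed-form oracle for φe* of this
family (binomial tail sums) guards the implementation in the test suite.

## Relations

Purview states are sets of (unit, state) pairs; congruence means same
unit *and* same state, applied uniformly to unions, intersections and
overlaps.  Self-relations use the cause∩effect overlap formula and are
always kept separate from multi-distinction relations.  The subset-sum
decomposition (per unit-state `o`, ratios sorted ascending) is an exact
identity with the brute-force enumeration; ties in ratios are broken by
stable sort and the total is asserted order-invariant.  Relation-table
values and the growth-rate bound use exact big-integer/rational
arithmetic (`Fraction`), since the quantities are double-exponential in
N; floats appear only when φ values come from actual systems.  The
growth-rate bound follows the printed formula
`(N²/2)·2^N + (N/2)·2^N·((2^(2^N−1)−1)/(2^N−1) − 1)`; the relation-sum
table values are derived from the decomposition with the stated φ_d
profiles (all-mechanism purviews = S with φ_d = |M|N, or self purviews
with φ_d = |M|²) and *include* the self-relation term.

## Problem sizes

Chosen so the full suite runs in about a minute and the bound-compliance
sweep stays exhaustive rather than sampled: exhaustive-MIP equivalence on
threshold systems up to N = 5; the weighted sweep at N = 12 via the
reduced family (sub-second); the Lemma-2/Theorem-1 compliance sweep over
200 seeded random systems of 2–4 units checking every mechanism, purview,
partition class and purview state; relation identities on all systems
with up to 12 distinctions; single-system `Σφe` tightness at N = 4–6
using the permutation symmetry of the threshold family (one mechanism per
size, scaled by C(N,k) — an exact reduction, asserted against the
explicit sum at small N).  Random-family sweeps default to 100 seeds as
the experimental design specifies; tests exercise them with 5–10 seeds at
N ≤ 3, which already separates the deterministic and stochastic families.

## Known limitations

* The cause side is the least-constrained part of the design.  Under the
  mirrored definition used here, deterministic constructions are heavily
  cause-degenerate: any sub-mechanism of units with identical likelihoods
  specifies the same cause, so composite mechanisms of the threshold
  family have φc = 0 and `Σφ = Σ min(φe, φc)` falls well below `Σφe`
  (the fig-2 sweep reports both columns side by side rather than
  asserting their equality).
* The numerical sum bound is tight in the per-size sense — each of its
  terms `C(N,K)·φe*(N,K)` is attained exactly by the size-K mechanisms of
  the corresponding construction — but no *single* system reaches it:
  the acceptance suite measures best single-system ratios near 0.56–0.60
  for N = 4–6, which is the inter-size trade-off the theory itself
  predicts.  The corresponding acceptance check encodes a stricter 0.9
  reading and is expected to fail; it is kept failing rather than
  weakened.
* φ values are floats (logs of rationals); only the combinatorial bounds
  and relation tables are exact.  MIP selection compares at 1e-9, so
  degenerate near-ties beyond that resolution are resolved by the
  documented tie-breaks, not by exact arithmetic.
* System-level integrated information is out of scope except for the
  printed `|S|(|S|−1)` partition bound; no complex search, no unfolding
  of full cause-effect structures with exclusion, no non-binary units.
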