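# iitbounds

Mechanism and relation integrated information on small binary networks:
an exact φ calculus, the deterministic transition-matrix families that
maximize it, and closed-form / numerical upper bounds on how large φ and
its sums can get.

Integrated information theory (IIT) quantifies the causal irreducibility
of a *mechanism* — a subset of units `M` of a discrete dynamical system in
a state `m`.  The mechanism's effect repertoire `πe(Z|m)` is the
distribution it induces over a purview `Z` at the next time step, computed
with *causal marginalization* (units outside the mechanism are averaged
over a uniform marginal, separately per purview unit, and recombined as a
product).  The integrated effect information of the pair is

    φe(m, Z) = πe(z′|m) · |log₂( πe(z′|m) / πe^θ′(z′|m) )|₊

where `z′` is the maximal effect state (the purview state whose
probability the mechanism raises most above chance) and `θ′` is the
minimum information partition (MIP): the division of the pair into
independent parts that loses the least information per severed
mechanism→purview connection, `N(θ)`.  The cause side `φc` mirrors this
backwards in time, and `φ(m) = min(φe, φc)`.

This package is aimed at researchers studying the combinatorics and upper
bounds of this calculus.  Its core results, all recomputable here on one
CPU in seconds to minutes:

* **Pair bound.** For any partition the information loss is at most
  `N(θ)`, hence `φe(m,Z) ≤ |M||Z|` — φ counts causal connections.
* **Sum bounds.** Summing over all mechanisms: `Σφ ≤ N²·2^N/2`
  (system-wide purviews) and `Σφ ≤ N(N+1)·2^N/4` (size-matched purviews).
  Neither is achievable: mechanisms that share parts cannot all be
  maximally irreducible.
* **Optimal constructions.** A deterministic family (`threshold_system`)
  in which every size-K mechanism specifies itself with probability 1 in
  the all-ON state; its φe*(N,K) attains `K²` exactly at `K ∈ {1, N}` and
  stays strictly below it otherwise.  For these systems the MIP is found
  among only `⌊K/2⌋+1` candidate partitions, making the *numerical sum
  bound* `Σ_K C(N,K)·φe*(N,K)` cheap (quadratic number of φ evaluations).
* **Relation sums.** Relations bind distinctions whose cause/effect
  purviews overlap congruently.  The sum of relation φ over all subsets of
  distinctions decomposes exactly from exponential to polynomial cost, and
  its linear-programming optimum gives closed-form relation-sum bounds
  that grow as `O(N²·2^(2^N))`.

## Worked example

Build the 3-unit threshold system with K = 2 (a unit fires iff it was ON
and at least two units were ON) and ask for the integrated effect
information of the mechanism {0,1} over itself in the all-ON state:

```sh
$ iitbounds construct --family threshold --n 3 --k 2 --out thr32.csv
$ iitbounds phi --tpm thr32.csv --state 111 --mechanism 0,1 --purview 0,1 --side effect
{
  "effect": {
    "mechanism_units": [0, 1],
    "mechanism_state": [1, 1],
    "side": "effect",
    "purview_units": [0, 1],
    "maximal_state": [1, 1],
    "phi": 0.8300749985576875,
    "selectivity": 1.0,
    "informativeness": 0.8300749985576875,
    "mip_parts": [[[0], [0]], [[1], [1]]],
    "severed": 2,
    "normalized_loss": 0.41503749927884376,
    ...
  }
}
```

Reading the numbers: the mechanism specifies the all-ON purview state with
probability 1 (`selectivity` = 1), and its MIP is the unit-aligned
bipartition `{0}→{0} | {1}→{1}` severing 2 of the 4 connections.  Each cut
unit's ON-probability drops from 1 to 3/4, so the partitioned probability
is 9/16 and φe = log₂(16/9) ≈ 0.830 bits — well below the 4-bit pair bound
`|M||Z| = 4`, because the two size-2 mechanisms of this system share a
unit.  The same quantities are available in Python:

```python
>>> from iitbounds import phi_e_star, numerical_sum_bound
>>> [round(phi_e_star(3, k), 4) for k in (1, 2, 3)]
[1.0, 0.8301, 9.0]
>>> round(numerical_sum_bound(3), 4)   # 3·1 + 3·0.8301 + 1·9
14.4902
```

`iitbounds sweep --figure 1 --n-range 4:12 --out results/` writes the
φe*(N,K)-vs-K² sweep tables (CSV plus a JSON manifest with the full
configuration), and `iitbounds relations --tpm FILE --state BITS` unfolds
a small system's distinctions and their exact relation sum.

## Conventions

States are little-endian throughout (unit 0 is the least significant bit
of a state index).  TPM files are plain CSV, either `2^N × N` per-unit
ON-probabilities (state-by-node, the native form) or `2^N × 2^N`
row-stochastic joints, which are accepted only if they factorize into a
product of unit conditionals.  All tie-breaks (maximal states, MIPs,
purview argmax) are deterministic and documented in `docs/methods.md`.
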