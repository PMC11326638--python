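"""Relation integrated information over sets of distinctions and its bounds.

A relation binds a subset of distinctions whose combined cause-effect
purviews overlap *congruently* — over the same units in the same states.
Purview states are therefore handled as sets of ``(unit, state)`` pairs
throughout.  For a subset **d** of two or more distinctions,

    φr(**d**) = |∩_d (z_c* ∪ z_e*)| · min_d φ_d / |z_c* ∪ z_e*|,

and a single distinction carries the self-relation
φr(d) = |z_c* ∩ z_e*| · φ_d / |z_c* ∪ z_e*|.

Summing φr over every non-empty subset of distinctions is exponential in
|D| by brute force, but decomposes exactly into a per-unit-state form: for
each unit-state ``o``, sort the distinctions containing ``o`` by their
φ/|z| ratio ascending; then the non-self part of the sum is
Σ_o Σ_i (φ_(i)/|z_(i)|)·(2^{|Z(o)|-i} - 1).  The linear-programming optimum
of that inner sum subject to Σ ratios ≤ S(o) is attained when all ratios
are equal, giving the closed-form bound used for the relation-sum tables.

Arithmetic is exact (int/Fraction) whenever the φ values supplied are
exact; system-derived float φ values propagate as floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RelationInput",
    "OverlapProfile",
    "hypothetical_distinction",
    "relation_phi",
    "self_relation_phi",
    "sum_relations_bruteforce",
    "overlap_profile",
    "sum_relations_decomposition",
    "optimal_relation_term",
    "sum_relations_bound",
    "growth_bound",
    "table3_relation_bounds",
    "max_relation_count",
]


@dataclass(frozen=True)
class RelationInput:
    """A distinction reduced to what relations need: the cause and effect
    purviews in their maximal states and the distinction's φ."""

    cause_states: frozenset[tuple[int, int]]
    effect_states: frozenset[tuple[int, int]]
    phi: object  # float, int or Fraction, > 0

    @property
    def union(self) -> frozenset[tuple[int, int]]:
        return self.cause_states | self.effect_states

    @property
    def ratio(self):
        return self.phi / len(self.union)


def hypothetical_distinction(cause: Mapping[int, int], effect: Mapping[int, int],
                             phi) -> RelationInput:
    """Build a relation input from unit→state maps (used for bound profiles)."""
    return RelationInput(frozenset(cause.items()), frozenset(effect.items()), phi)


def _coerce(d) -> RelationInput:
    if isinstance(d, RelationInput):
        return d
    # duck-type phi.Distinction
    return RelationInput(frozenset(d.cause_states), frozenset(d.effect_states), d.phi)


def relation_phi(ds: Sequence) -> object:
    """φr of a subset of >= 2 distinctions: congruent overlap size times the
    smallest φ/|z| ratio; 0 when there is no congruent overlap."""
    ds = [_coerce(d) for d in ds]
    if len(ds) < 2:
        raise ValueError("a relation needs at least two distinctions (see self_relation_phi)")
    overlap = frozenset.intersection(*(d.union for d in ds))
    if not overlap:
        return 0
    return len(overlap) * min(d.ratio for d in ds)


def self_relation_phi(d) -> object:
    """φr of a single distinction: congruent cause∩effect overlap size times
    φ_d / |z_c* ∪ z_e*|."""
    d = _coerce(d)
    inter = d.cause_states & d.effect_states
    if not inter:
        return 0
    return len(inter) * d.ratio


def sum_relations_bruteforce(D: Sequence) -> object:
    """Σ φr over every non-empty subset of D by explicit enumeration
    (exponential; |D| <= 16)."""
    D = [_coerce(d) for d in D]
    if len(D) > 16:
        raise ValueError("brute force limited to |D| <= 16")
    total = sum(self_relation_phi(d) for d in D)
    for r in range(2, len(D) + 1):
        for sub in combinations(D, r):
            total += relation_phi(sub)
    return total


@dataclass
class OverlapProfile:
    """Per unit-state o: the φ/|z| ratios of the distinctions whose combined
    purview contains o (ascending), and their sum S(o)."""

    ratios: dict[tuple[int, int], list]

    def S(self, o: tuple[int, int]):
        return sum(self.ratios[o])

    def size(self, o: tuple[int, int]) -> int:
        return len(self.ratios[o])


def overlap_profile(D: Sequence) -> OverlapProfile:
    D = [_coerce(d) for d in D]
    ratios: dict[tuple[int, int], list] = {}
    for d in D:
        for o in d.union:
            ratios.setdefault(o, []).append(d.ratio)
    for o in ratios:
        ratios[o].sort()
    return OverlapProfile(ratios)


def sum_relations_decomposition(D: Sequence) -> object:
    """Σ φr over all non-empty subsets via the exact per-unit-state
    decomposition (polynomial in |D|): identical to the brute force."""
    D = [_coerce(d) for d in D]
    total = sum(self_relation_phi(d) for d in D)
    profile = overlap_profile(D)
    for o, ratios in profile.ratios.items():
        n = len(ratios)
        for i, r in enumerate(ratios, start=1):
            total += r * (2 ** (n - i) - 1)
    return total


def optimal_relation_term(S_o, size_Zo: int):
    """LP optimum of the per-unit-state term given Σ ratios <= S(o) and
    |Z(o)| distinctions: S(o)·((2^|Z(o)| - 1)/|Z(o)| - 1), attained when all
    ratios are equal."""
    if size_Zo < 1:
        raise ValueError("|Z(o)| must be >= 1")
    if isinstance(S_o, (int, Fraction)):
        return S_o * (Fraction(2**size_Zo - 1, size_Zo) - 1)
    return S_o * ((2**size_Zo - 1) / size_Zo - 1)


def sum_relations_bound(profile: OverlapProfile, sum_phi_d) -> object:
    """Σφ_d plus the per-unit-state LP optima: an upper bound on the full
    relation sum for any distinction set with this overlap profile."""
    total = sum_phi_d
    for o in profile.ratios:
        total = total + optimal_relation_term(profile.S(o), profile.size(o))
    return total


def growth_bound(N: int) -> Fraction:
    """Growth-rate bound for the relation sum of an N-unit system, from
    |Z(o)| = 2^N - 1 and S(o) <= (N/2)·2^N: exact rational (the values are
    double-exponential in N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    n_dist = 2**N - 1
    s_o = Fraction(N * 2**N, 2)
    sum_phi_d = Fraction(N * N * 2**N, 2)
    return sum_phi_d + s_o * (Fraction(2**n_dist - 1, n_dist) - 1)


def max_relation_count(N: int) -> int:
    """An N-unit system has at most 2^(2^N - 1) - 1 non-empty relation subsets."""
    return 2 ** (2**N - 1) - 1


def _table3_distinctions(N: int, profile_kind: str) -> list[RelationInput]:
    all_on = {u: 1 for u in range(N)}
    out = []
    for r in range(1, N + 1):
        for M in combinations(range(N), r):
            if profile_kind == "bound1":
                z = all_on
                phi = r * N
            elif profile_kind == "bound2":
                z = {u: 1 for u in M}
                phi = r * r
            else:
                raise ValueError(f"unknown profile kind {profile_kind!r}")
            out.append(hypothetical_distinction(z, z, Fraction(phi)))
    return out


def table3_relation_bounds(N: int, profile_kind: str) -> Fraction:
    """Relation-sum value of the hypothetical maximal distinction sets:
    ``bound1`` gives every mechanism φ_d = |M|·N over system-wide purviews,
    ``bound2`` gives φ_d = |M|² over self purviews.  Evaluated exactly from
    the decomposition (self-relations included)."""
    D = _table3_distinctions(N, profile_kind)
    return sum_relations_decomposition(D)
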