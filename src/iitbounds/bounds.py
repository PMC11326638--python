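"""Closed-form and numerical upper bounds for distinction φ.

The basic bound is combinatorial: the loss any partition can inflict on a
repertoire is at most the number of mechanism→purview connections it
severs, so φ of a mechanism-purview pair is at most |M|·|Z|.  Summing over
all mechanisms gives the closed forms below.  For the high-selectivity
(threshold) construction a reduced candidate-partition family of only
⌊K/2⌋+1 members — the complete cut plus the aligned bipartitions by part
size — is sufficient to locate the MIP of a size-K mechanism over itself,
which makes the numerical bound Σ_K C(N,K)·φe*(K) cheap to evaluate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .constructions import threshold_system
from .partitions import Partition, class_to_partition
from .phi import integrated_effect_information
from .tpm import Mechanism, Purview

__all__ = [
    "BoundReport",
    "theorem1_pair_bound",
    "eq6_sum_bound",
    "eq7_sum_bound",
    "system_phi_s_bound",
    "candidate_partition_classes",
    "candidate_partitions_threshold",
    "phi_e_star",
    "numerical_sum_bound",
]


@dataclass(frozen=True)
class BoundReport:
    name: str
    n_units: int
    parameters: dict
    value: object  # int, Fraction or float (bits)
    achievable: bool


def _as_int(x: Fraction):
    return int(x) if x.denominator == 1 else x


def theorem1_pair_bound(m_size: int, z_size: int) -> int:
    """φ of a single mechanism-purview pair is at most |M|·|Z| connections."""
    if m_size < 1 or z_size < 1:
        raise ValueError("sizes must be >= 1")
    return m_size * z_size


def eq6_sum_bound(N: int):
    """Σ_{M⊆S} |M|·N = N²·2^N / 2 — system-wide purviews, not achievable."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return _as_int(Fraction(N * N * 2**N, 2))


def eq7_sum_bound(N: int):
    """Σ_{M⊆S} |M|² = N(N+1)·2^N / 4 — size-matched unique purviews."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return _as_int(Fraction(N * (N + 1) * 2**N, 4))


def system_phi_s_bound(N: int) -> int:
    """Maximum connections cut by any system partition: |S|(|S|-1)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return N * (N - 1)


# ---------------------------------------------------------------------------
# reduced candidate-partition family for the threshold construction
# ---------------------------------------------------------------------------

def candidate_partition_classes(units: tuple[int, ...]) -> list[tuple[tuple[frozenset, ...], int]]:
    """The ⌊K/2⌋+1 candidate MIP classes for a reflexive size-K pair: the
    complete cut (j = 0) plus the aligned bipartitions with part sizes
    (j, K-j), j = 1..⌊K/2⌋.  Which units form the small part is immaterial
    by the permutation symmetry of the construction."""
    units = tuple(sorted(units))
    K = len(units)
    empty: frozenset = frozenset()
    out = [(tuple(empty for _ in units), K * K)]
    for j in range(1, K // 2 + 1):
        g1 = frozenset(units[:j])
        g2 = frozenset(units[j:])
        assignment = tuple(g1 if u in g1 else g2 for u in units)
        out.append((assignment, K * K - j * j - (K - j) * (K - j)))
    return out


def candidate_partitions_threshold(K: int) -> list[Partition]:
    """The reduced candidate family as explicit partitions over units 0..K-1."""
    if K < 1:
        raise ValueError("K must be >= 1")
    units = tuple(range(K))
    return [class_to_partition(units, units, assignment)
            for assignment, _ in candidate_partition_classes(units)]


def phi_e_star(N: int, K: int, exhaustive: bool = False) -> float:
    """φe of a size-K mechanism over itself in the threshold construction,
    all-ON state.  Uses the reduced candidate family unless ``exhaustive``.

    Satisfies φe*(N, N) = N², φe*(N, 1) = 1 and φe*(N, K) < K² for
    1 < K < N.
    """
    if not 1 <= K <= N:
        raise ValueError("need 1 <= K <= N")
    tpm = threshold_system(N, K, verify=False)
    units = tuple(range(K))
    m = Mechanism(units, (1,) * K)
    candidates = None if exhaustive else candidate_partition_classes(units)
    res = integrated_effect_information(tpm, m, Purview(units), candidates=candidates)
    return res.phi


def numerical_sum_bound(N: int) -> float:
    """Σ_K C(N,K)·φe*(N,K): the reflexive-system numerical upper bound for
    the sum of integrated effect information over all mechanisms."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return sum(comb(N, K) * phi_e_star(N, K) for K in range(1, N + 1))


def bound_report(which: str, N: int, K: int | None = None) -> BoundReport:
    """Named bound evaluation for reports and the CLI."""
    if which == "theorem1_pair":
        return BoundReport(which, N, {"m_size": K, "z_size": K},
                           theorem1_pair_bound(K, K), True)
    if which == "eq6_sum":
        return BoundReport(which, N, {}, eq6_sum_bound(N), False)
    if which == "eq7_sum":
        return BoundReport(which, N, {}, eq7_sum_bound(N), False)
    if which == "system_phi_s":
        return BoundReport(which, N, {}, system_phi_s_bound(N), True)
    if which == "numerical_sum":
        return BoundReport(which, N, {}, numerical_sum_bound(N), True)
    raise ValueError(f"unknown bound {which!r}")
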