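"""Partitions of a mechanism-purview pair and their severed-connection counts.

A partition θ divides the mechanism units M and the purview units Z into
k >= 2 parts (M_i, Z_i): the M_i are disjoint with union M, the Z_i are
disjoint with union Z, either side of a part may be empty but not both, and
the identity (a single part containing the whole pair) is excluded.  This is
the set of all divisions of the combined slots M ⊔ Z into at least two
non-empty blocks.  After partitioning, each part's purview units are
constrained only by that part's mechanism units; all other mechanism units
are causally marginalized.

The severed-connection count is

    N(θ) = |M||Z| - Σ_i |M_i||Z_i|,

the number of mechanism→purview pairs that end up in different parts.  Every
valid partition severs at least one connection.

Two schemes are exposed: ``"full"`` (everything above) and ``"bipartitions"``
(the two-part subset, for ablation).

For minimum-information-partition searches an exact reduction is used: the
partitioned repertoire and N(θ) both depend only on the map sending each
purview unit to the mechanism subset it remains connected to, so the search
enumerates one representative per such map (see :func:`partition_classes`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

__all__ = ["Partition", "enumerate_partitions", "partition_classes", "class_to_partition"]


@dataclass(frozen=True)
class Partition:
    """An unordered division of (M, Z) into parts ``(mech_subset, purview_subset)``."""

    parts: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    def __post_init__(self):
        canon = tuple(sorted(
            (tuple(sorted(ms)), tuple(sorted(zs))) for ms, zs in self.parts
        ))
        object.__setattr__(self, "parts", canon)

    @property
    def mechanism_units(self) -> tuple[int, ...]:
        return tuple(sorted(u for ms, _ in self.parts for u in ms))

    @property
    def purview_units(self) -> tuple[int, ...]:
        return tuple(sorted(u for _, zs in self.parts for u in zs))

    @property
    def severed(self) -> int:
        m, z = len(self.mechanism_units), len(self.purview_units)
        return m * z - sum(len(ms) * len(zs) for ms, zs in self.parts)

    def purview_assignment(self) -> dict[int, tuple[int, ...]]:
        """Map purview unit -> mechanism subset it stays connected to."""
        return {u: ms for ms, zs in self.parts for u in zs}

    def validate(self, m_units: Sequence[int], z_units: Sequence[int]) -> None:
        if self.mechanism_units != tuple(sorted(m_units)) or \
                self.purview_units != tuple(sorted(z_units)):
            raise ValueError("partition does not cover the mechanism-purview pair")
        seen_m: set[int] = set()
        seen_z: set[int] = set()
        for ms, zs in self.parts:
            if not ms and not zs:
                raise ValueError("empty part")
            if seen_m & set(ms) or seen_z & set(zs):
                raise ValueError("overlapping parts")
            seen_m |= set(ms)
            seen_z |= set(zs)
        if len(self.parts) < 2:
            raise ValueError("a partition needs at least two parts")
        if self.severed < 1:
            raise ValueError("partition severs no connection")


def _set_partitions(items: list) -> Iterator[list[list]]:
    """All set partitions of ``items`` into non-empty unordered blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def enumerate_partitions(M: Sequence[int], Z: Sequence[int],
                         scheme: str = "full") -> list[Partition]:
    """Explicitly enumerate Θ(M, Z) under the given scheme.

    Intended for small pairs (tests, reports); MIP searches use the
    class-based reduction instead.
    """
    m_units = tuple(sorted(int(u) for u in M))
    z_units = tuple(sorted(int(u) for u in Z))
    if not m_units or not z_units:
        raise ValueError("mechanism and purview must be non-empty")
    slots = [("m", u) for u in m_units] + [("z", u) for u in z_units]

    def to_partition(blocks) -> Partition:
        return Partition(tuple(
            (tuple(u for kind, u in blk if kind == "m"),
             tuple(u for kind, u in blk if kind == "z"))
            for blk in blocks
        ))

    if scheme == "full":
        out = [to_partition(blocks) for blocks in _set_partitions(slots)
               if len(blocks) >= 2]
    elif scheme == "bipartitions":
        out = []
        n = len(slots)
        seen = set()
        # choose the block containing slot 0; the complement is the other block
        for r in range(0, n):
            for extra in combinations(range(1, n), r):
                blk1 = [slots[0]] + [slots[i] for i in extra]
                blk2 = [s for i, s in enumerate(slots) if i != 0 and i not in extra]
                if not blk2:
                    continue
                p = to_partition([blk1, blk2])
                if p not in seen:
                    seen.add(p)
                    out.append(p)
    else:
        raise ValueError(f"unknown partition scheme: {scheme!r}")
    return [p for p in out if p.severed >= 1]


def partition_classes(m_units: Sequence[int], z_units: Sequence[int],
                      scheme: str = "full") -> Iterator[tuple[tuple[frozenset, ...], int]]:
    """Yield ``(assignment, severed)`` for one representative per MIP class.

    ``assignment[j]`` is the (frozen) mechanism subset that purview unit
    ``z_units[j]`` remains connected to; distinct non-empty subsets in one
    assignment are pairwise disjoint.  The identity assignment (every purview
    unit keeps the full mechanism) is excluded.  Every class is realized by at
    least one valid partition of the chosen scheme and all partitions in a
    class share both the partitioned repertoire and N(θ).
    """
    m_units = tuple(sorted(int(u) for u in m_units))
    z_units = tuple(sorted(int(u) for u in z_units))
    k, nz = len(m_units), len(z_units)
    full = frozenset(m_units)
    empty: frozenset = frozenset()

    if scheme == "bipartitions":
        # parts (M1, Z1) | (M2, Z2); assignment maps Z1 -> M1, Z2 -> M2
        seen = set()
        for m1_size in range(0, k + 1):
            for m1 in combinations(m_units, m1_size):
                m1f, m2f = frozenset(m1), full - frozenset(m1)
                for z1_size in range(0, nz + 1):
                    for z1 in combinations(z_units, z1_size):
                        z1s = set(z1)
                        if not m1f and not z1s:
                            continue
                        if m1f == full and z1s == set(z_units):
                            continue
                        assignment = tuple(m1f if u in z1s else m2f for u in z_units)
                        sev = k * nz - sum(len(a) for a in assignment)
                        if sev < 1:
                            continue
                        if assignment not in seen:
                            seen.add(assignment)
                            yield assignment, sev
        return
    if scheme != "full":
        raise ValueError(f"unknown partition scheme: {scheme!r}")

    subsets_of = {}  # cache: available-mask -> non-empty subsets

    def nonempty_subsets(avail: tuple[int, ...]):
        if avail not in subsets_of:
            subs = []
            for r in range(1, len(avail) + 1):
                subs.extend(frozenset(c) for c in combinations(avail, r))
            subsets_of[avail] = subs
        return subsets_of[avail]

    assignment: list[frozenset] = [empty] * nz

    def rec(j: int, used: frozenset, groups: tuple[frozenset, ...]):
        if j == nz:
            if all(a == full for a in assignment):
                return  # identity
            sev = k * nz - sum(len(a) for a in assignment)
            if sev >= 1:
                yield tuple(assignment), sev
            return
        # unconstrained
        assignment[j] = empty
        yield from rec(j + 1, used, groups)
        # join an existing group
        for g in groups:
            assignment[j] = g
            yield from rec(j + 1, used, groups)
        # open a new group from unused mechanism units
        avail = tuple(sorted(full - used))
        for g in nonempty_subsets(avail):
            assignment[j] = g
            yield from rec(j + 1, used | g, groups + (g,))

    yield from rec(0, empty, ())


def class_to_partition(m_units: Sequence[int], z_units: Sequence[int],
                       assignment: Sequence[frozenset]) -> Partition:
    """A canonical valid partition realizing a MIP class."""
    m_units = tuple(sorted(int(u) for u in m_units))
    z_units = tuple(sorted(int(u) for u in z_units))
    groups: dict[frozenset, list[int]] = {}
    for u, g in zip(z_units, assignment):
        groups.setdefault(g, []).append(u)
    parts = []
    used: set[int] = set()
    for g, zs in groups.items():
        if g:
            parts.append((tuple(sorted(g)), tuple(zs)))
            used |= set(g)
        else:
            parts.append(((), tuple(zs)))
    leftover = tuple(u for u in m_units if u not in used)
    if leftover:
        parts.append((leftover, ()))
    return Partition(tuple(parts))
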