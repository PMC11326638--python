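"""Mechanism integrated information: maximal states, MIP search, φe and φc.

The integrated effect information of a mechanism ``m`` over a purview ``Z``
is evaluated at the maximal effect state ``z'`` (the state whose probability
the mechanism raises most above chance) as

    φe(m, Z) = πe(z'|m) · |log2( πe(z'|m) / πe^θ'(z'|m) )|_+

where θ' is the minimum information partition: the partition minimizing the
same quantity *normalized* by its severed-connection count N(θ).  The
normalization is used only to select θ'; the reported φ is the un-normalized
loss at θ'.  The cause side mirrors this with cause repertoires; a mechanism
state that no purview state can produce yields the flagged undefined cause
and φc = 0.

Tie-breaking (deterministic, recorded on the result):

* maximal state: lexicographically smallest purview state (little-endian);
* MIP: among partitions whose normalized loss agrees within ``1e-9``, the
  one severing the most connections, then first in canonical enumeration
  order;
* purview search: larger purview first, then lexicographically smallest
  unit tuple.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .partitions import Partition, class_to_partition, partition_classes
from .tpm import (
    Mechanism,
    Purview,
    Repertoire,
    SystemTPM,
    cause_repertoire,
    effect_repertoire,
    unconstrained_cause,
    unconstrained_effect,
)

logger = logging.getLogger(__name__)

__all__ = [
    "difference_measure",
    "maximal_effect_state",
    "maximal_cause_state",
    "partitioned_effect_repertoire",
    "partitioned_cause_repertoire",
    "mip",
    "integrated_effect_information",
    "integrated_cause_information",
    "mechanism_phi",
    "PhiResult",
    "Distinction",
    "MechanismPhi",
    "phi_report",
]

TIE_TOL = 1e-9
MEASURES = ("positive-part", "absolute-value", "pointwise-mutual-information", "kl")
_MEASURE_ALIASES = {"abs": "absolute-value", "pmi": "pointwise-mutual-information"}


def difference_measure(p: float, q: float, variant: str = "positive-part") -> float:
    """State-wise difference between probabilities ``p`` (intact) and ``q``
    (partitioned).  ``0·log`` terms are defined as 0.  The default is the
    selectivity-weighted positive-part log-ratio; the alternatives weight or
    clamp the log-ratio differently and are provided for sensitivity checks.
    """
    variant = _MEASURE_ALIASES.get(variant, variant)
    if variant not in MEASURES:
        raise ValueError(f"unknown difference measure {variant!r}")
    if p < 0 or p > 1 or q < 0 or q > 1:
        raise ValueError("p and q must be probabilities")
    if p == 0.0:
        return 0.0
    if q == 0.0:
        raise RuntimeError(
            "partitioned probability 0 with intact probability > 0: "
            "impossible for causal-marginalization partitions"
        )
    ratio = math.log2(p / q)
    if variant == "positive-part":
        return p * max(ratio, 0.0)
    if variant == "absolute-value":
        return p * abs(ratio)
    if variant == "pointwise-mutual-information":
        return max(ratio, 0.0)
    return p * ratio  # kl: the state's contribution to the KL divergence


# ---------------------------------------------------------------------------
# maximal states
# ---------------------------------------------------------------------------

def _argmax_state(values: np.ndarray, units: Sequence[int]) -> tuple[tuple[int, ...], float]:
    best = float(values.max())
    idx = int(np.flatnonzero(values >= best - TIE_TOL)[0])
    state = tuple((idx >> k) & 1 for k in range(len(units)))
    return state, best


def maximal_effect_state(tpm: SystemTPM, m: Mechanism, Z: Purview
                         ) -> tuple[tuple[int, ...], float]:
    """State of ``Z`` maximizing πe(z|m)·log2(πe(z|m)/πe(z;M)) and that value
    (the informativeness-vs-chance of the mechanism over the purview)."""
    rep = effect_repertoire(tpm, m, Z).probs
    unc = unconstrained_effect(tpm, Z, m.units).probs
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(rep > 0, rep * np.log2(np.where(rep > 0, rep, 1.0) / unc), 0.0)
    return _argmax_state(vals, Z.units)


def maximal_cause_state(tpm: SystemTPM, m: Mechanism, Z: Purview
                        ) -> tuple[tuple[int, ...], float] | None:
    """Mirror of :func:`maximal_effect_state` for the cause side; ``None``
    when the cause repertoire is undefined."""
    rep = cause_repertoire(tpm, m, Z)
    if not rep.defined:
        return None
    unc = unconstrained_cause(tpm, Z, m.units)
    p = rep.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / unc.probs), 0.0)
    return _argmax_state(vals, Z.units)


# ---------------------------------------------------------------------------
# partitioned repertoires
# ---------------------------------------------------------------------------

def _restrict(m: Mechanism, subset: Iterable[int]) -> Mechanism:
    subset = sorted(subset)
    lookup = dict(zip(m.units, m.state))
    return Mechanism(tuple(subset), tuple(lookup[u] for u in subset))


def partitioned_effect_repertoire(tpm: SystemTPM, m: Mechanism, Z: Purview,
                                  theta: Partition) -> Repertoire:
    """Effect repertoire after partitioning: each purview unit is constrained
    only by its part's mechanism units (everything else causally
    marginalized), parts combined by product."""
    theta.validate(m.units, Z.units)
    assignment = theta.purview_assignment()
    p_on = []
    for u in Z.units:
        sub = _restrict(m, assignment[u])
        p_on.append(tpm.unit_on_given(sub.units, sub.state, u))
    dist = np.ones(1)
    for p in p_on:
        dist = np.concatenate([dist * (1.0 - p), dist * p])
    return Repertoire(Purview(Z.units), dist)


def _part_cause_dist(tpm: SystemTPM, m: Mechanism, msub: Iterable[int],
                     zgroup: Sequence[int]) -> np.ndarray:
    """Normalized cause repertoire of one part; uniform for an empty or
    undefined part (maximum-entropy fallback, see methods note)."""
    zgroup = tuple(sorted(zgroup))
    msub = sorted(msub)
    if not msub:
        return np.full(2 ** len(zgroup), 2.0 ** -len(zgroup))
    rep = cause_repertoire(tpm, _restrict(m, msub), Purview(zgroup))
    if not rep.defined:
        return np.full(2 ** len(zgroup), 2.0 ** -len(zgroup))
    return rep.probs


def partitioned_cause_repertoire(tpm: SystemTPM, m: Mechanism, Z: Purview,
                                 theta: Partition) -> Repertoire:
    """Cause repertoire after partitioning: product over parts of each part's
    normalized cause repertoire."""
    theta.validate(m.units, Z.units)
    nz = len(Z.units)
    pos = {u: i for i, u in enumerate(Z.units)}
    dist = np.ones(2 ** nz)
    states = np.arange(2 ** nz)
    for ms, zs in theta.parts:
        if not zs:
            continue
        part = _part_cause_dist(tpm, m, ms, zs)
        sub_idx = np.zeros(2 ** nz, dtype=int)
        for k, u in enumerate(sorted(zs)):
            sub_idx |= ((states >> pos[u]) & 1) << k
        dist *= part[sub_idx]
    return Repertoire(Purview(Z.units), dist)


# ---------------------------------------------------------------------------
# MIP search
# ---------------------------------------------------------------------------

@dataclass
class PhiResult:
    """Integrated cause/effect information of a mechanism over one purview."""

    mechanism: Mechanism
    purview: Purview  # carries the maximal state
    phi: float
    mip: Partition | None
    side: str
    selectivity: float
    informativeness: float
    normalized_loss: float = 0.0
    tie_broken: bool = False
    defined: bool = True  # False for the flagged undefined cause

    @property
    def severed(self) -> int:
        return self.mip.severed if self.mip is not None else 0


def _search_mip(loss_of, classes, m_units, z_units, selectivity, measure):
    """Minimize measure(sel, q)/N over partition classes.

    ``loss_of(assignment)`` returns the partitioned probability q at the
    maximal state.  Returns (Partition, phi, normalized, tie_broken).
    """
    best_norm = math.inf
    best_sev = -1
    best_assignment = None
    best_phi = 0.0
    tie = False
    for assignment, sev in classes:
        q = loss_of(assignment)
        phi = difference_measure(selectivity, q, measure)
        norm = phi / sev
        if norm < best_norm - TIE_TOL:
            best_norm, best_sev, best_assignment, best_phi = norm, sev, assignment, phi
            tie = False
        elif norm <= best_norm + TIE_TOL:
            tie = True
            if sev > best_sev:
                best_norm = min(best_norm, norm)
                best_sev, best_assignment, best_phi = sev, assignment, phi
    if best_assignment is None:
        raise RuntimeError("empty partition set")
    if tie:
        logger.debug("MIP tie broken toward largest N(theta) for M=%s Z=%s",
                     m_units, z_units)
    return (class_to_partition(m_units, z_units, best_assignment),
            best_phi, best_norm, tie)


def _effect_mip(tpm, m, Z, state, scheme, measure, candidates=None):
    z_units = Z.units
    p_unit = np.empty(len(z_units))
    for j, u in enumerate(z_units):
        p_on = tpm.unit_on_given(m.units, m.state, u)
        p_unit[j] = p_on if state[j] == 1 else 1.0 - p_on
    selectivity = float(p_unit.prod())

    cache: dict[frozenset, np.ndarray] = {}

    def unit_probs(msub: frozenset) -> np.ndarray:
        arr = cache.get(msub)
        if arr is None:
            sub = _restrict(m, msub)
            arr = np.empty(len(z_units))
            for j, u in enumerate(z_units):
                p_on = tpm.unit_on_given(sub.units, sub.state, u)
                arr[j] = p_on if state[j] == 1 else 1.0 - p_on
            cache[msub] = arr
        return arr

    def q_of(assignment) -> float:
        q = 1.0
        for j, g in enumerate(assignment):
            q *= unit_probs(g)[j]
        return q

    classes = candidates if candidates is not None else \
        partition_classes(m.units, z_units, scheme)
    return _search_mip(q_of, classes, m.units, z_units, selectivity, measure), selectivity


def _cause_mip(tpm, m, Z, state, scheme, measure, candidates=None):
    z_units = Z.units
    rep = cause_repertoire(tpm, m, Z)
    selectivity = rep.prob(state)
    pos = {u: i for i, u in enumerate(z_units)}
    part_cache: dict[tuple, float] = {}

    def part_value(msub: frozenset, zgroup: tuple[int, ...]) -> float:
        key = (msub, zgroup)
        val = part_cache.get(key)
        if val is None:
            dist = _part_cause_dist(tpm, m, msub, zgroup)
            idx = 0
            for k, u in enumerate(sorted(zgroup)):
                idx |= state[pos[u]] << k
            val = float(dist[idx])
            part_cache[key] = val
        return val

    def q_of(assignment) -> float:
        groups: dict[frozenset, list[int]] = {}
        for u, g in zip(z_units, assignment):
            groups.setdefault(g, []).append(u)
        q = 1.0
        for g, zs in groups.items():
            q *= part_value(g, tuple(zs))
        return q

    classes = candidates if candidates is not None else \
        partition_classes(m.units, z_units, scheme)
    return _search_mip(q_of, classes, m.units, z_units, selectivity, measure), selectivity


def mip(tpm: SystemTPM, m: Mechanism, Z: Purview, side: str = "effect",
        scheme: str = "full", measure: str = "positive-part") -> Partition:
    """The minimum information partition of ``(m, Z)`` on the given side."""
    result = (integrated_effect_information if side == "effect"
              else integrated_cause_information)(tpm, m, Z, scheme=scheme,
                                                 measure=measure)
    return result.mip


def integrated_effect_information(tpm: SystemTPM, m: Mechanism, Z: Purview,
                                  scheme: str = "full",
                                  measure: str = "positive-part",
                                  candidates=None) -> PhiResult:
    """φe(m, Z): the un-normalized positive-part loss at the MIP, evaluated
    at the maximal effect state.  ``candidates`` may supply a reduced
    iterable of partition classes (e.g. the threshold-system fast path)."""
    state, _ = maximal_effect_state(tpm, m, Z)
    (partition, phi, norm, tie), selectivity = _effect_mip(
        tpm, m, Z, state, scheme, measure, candidates)
    informativeness = phi / selectivity if selectivity > 0 else 0.0
    return PhiResult(m, Purview(Z.units, state), phi, partition, "effect",
                     selectivity, informativeness, norm, tie)


def integrated_cause_information(tpm: SystemTPM, m: Mechanism, Z: Purview,
                                 scheme: str = "full",
                                 measure: str = "positive-part",
                                 candidates=None) -> PhiResult:
    """φc(m, Z), mirroring the effect side with cause repertoires; the
    flagged undefined cause yields φc = 0."""
    ms = maximal_cause_state(tpm, m, Z)
    if ms is None:
        return PhiResult(m, Purview(Z.units), 0.0, None, "cause", 0.0, 0.0,
                         defined=False)
    state, _ = ms
    (partition, phi, norm, tie), selectivity = _cause_mip(
        tpm, m, Z, state, scheme, measure, candidates)
    informativeness = phi / selectivity if selectivity > 0 else 0.0
    return PhiResult(m, Purview(Z.units, state), phi, partition, "cause",
                     selectivity, informativeness, norm, tie)


# ---------------------------------------------------------------------------
# purview search / distinctions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Distinction:
    """An irreducible mechanism with its maximally irreducible cause and
    effect purviews in their maximal states; φ = min(φc, φe)."""

    mechanism: Mechanism
    cause: Purview
    effect: Purview
    phi: float
    phi_cause: float = 0.0
    phi_effect: float = 0.0

    @property
    def cause_states(self) -> frozenset[tuple[int, int]]:
        return self.cause.unit_states()

    @property
    def effect_states(self) -> frozenset[tuple[int, int]]:
        return self.effect.unit_states()


@dataclass
class MechanismPhi:
    """Result of the full purview search for one mechanism."""

    mechanism: Mechanism
    effect: PhiResult | None
    cause: PhiResult | None
    phi: float

    @property
    def irreducible(self) -> bool:
        return self.phi > 0.0

    @property
    def distinction(self) -> Distinction | None:
        if not self.irreducible:
            return None
        return Distinction(self.mechanism, self.cause.purview, self.effect.purview,
                           self.phi, self.cause.phi, self.effect.phi)


def _default_purviews(n: int) -> list[tuple[int, ...]]:
    out = []
    for r in range(1, n + 1):
        out.extend(combinations(range(n), r))
    return out


def _purview_key(units: tuple[int, ...]):
    # larger purview wins ties, then lexicographically smallest unit tuple
    return (-len(units), units)


def _best_side(tpm, m, purviews, side, scheme, measure) -> PhiResult | None:
    fn = integrated_effect_information if side == "effect" else integrated_cause_information
    best: PhiResult | None = None
    for units in sorted(purviews, key=_purview_key):
        res = fn(tpm, m, Purview(tuple(units)), scheme=scheme, measure=measure)
        if best is None or res.phi > best.phi + TIE_TOL:
            best = res
    return best


def mechanism_phi(tpm: SystemTPM, m: Mechanism,
                  purview_space: Iterable[Sequence[int]] | str | None = None,
                  scheme: str = "full",
                  measure: str = "positive-part") -> MechanismPhi:
    """Maximally irreducible cause and effect of ``m`` and φ(m) = min(φc, φe).

    ``purview_space`` defaults to all non-empty subsets of the system;
    ``"self"`` restricts the search to Z = M (reflexive systems).
    """
    if purview_space is None:
        purviews = _default_purviews(tpm.n_units)
    elif purview_space == "self":
        purviews = [m.units]
    else:
        purviews = [tuple(sorted(int(u) for u in p)) for p in purview_space]
    eff = _best_side(tpm, m, purviews, "effect", scheme, measure)
    if eff is not None and eff.phi <= 0.0:
        return MechanismPhi(m, eff, None, 0.0)
    cau = _best_side(tpm, m, purviews, "cause", scheme, measure)
    phi = min(eff.phi, cau.phi)
    return MechanismPhi(m, eff, cau, phi)


def phi_report(result: PhiResult) -> dict:
    """JSON-serializable report of a single-side φ computation."""
    return {
        "mechanism_units": list(result.mechanism.units),
        "mechanism_state": list(result.mechanism.state),
        "side": result.side,
        "purview_units": list(result.purview.units),
        "maximal_state": list(result.purview.state) if result.purview.state else None,
        "phi": result.phi,
        "selectivity": result.selectivity,
        "informativeness": result.informativeness,
        "mip_parts": [[list(ms), list(zs)] for ms, zs in result.mip.parts]
        if result.mip else None,
        "severed": result.severed,
        "normalized_loss": result.normalized_loss,
        "tie_broken": result.tie_broken,
        "defined": result.defined,
    }
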