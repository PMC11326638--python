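"""Transition models of binary-unit networks and causal marginalization.

A system of ``N`` binary units is represented by its per-unit conditional
probabilities of being ON at ``t+1`` given the full system state at ``t``
(the *state-by-node* form).  Under the standing conditional-independence
assumption the joint transition probability is the product of these
per-unit conditionals, so this representation is lossless.

State indexing is **little-endian** throughout: unit ``0`` is the least
significant bit of a state index, so state index ``s`` has unit ``i`` ON
iff ``(s >> i) & 1``.  The same convention applies to repertoires, whose
bit ``k`` is the ``k``-th smallest unit of the purview.

Causal marginalization renders units causally inert by averaging the
conditional distribution of each output unit over a uniform distribution
of the marginalized inputs, separately per output unit, and combining
output units by a product (which removes residual correlations that a
joint marginalization would retain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SystemTPM",
    "Mechanism",
    "Purview",
    "Repertoire",
    "effect_repertoire_single",
    "effect_repertoire",
    "unconstrained_effect",
    "cause_repertoire",
    "all_states",
]

#: absolute tolerance for float equality of probabilities
PROB_ATOL = 1e-9


@lru_cache(maxsize=32)
def all_states(n: int) -> np.ndarray:
    """Bit matrix of shape ``(2**n, n)``; row ``s`` column ``i`` is bit ``i`` of ``s``."""
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int8)


def state_index(units: Sequence[int], state: Sequence[int]) -> int:
    """Little-endian index of ``state`` within the ordered unit list ``units``."""
    return int(sum(int(b) << k for k, b in enumerate(state)))


class SystemTPM:
    """Unit-conditional transition model of ``n_units`` binary units.

    Parameters
    ----------
    on_probs
        Array of shape ``(2**n, n)``; entry ``[s, i]`` is the probability
        that unit ``i`` is ON at ``t+1`` given previous state index ``s``
        (little-endian).
    """

    def __init__(self, on_probs: np.ndarray):
        on_probs = np.asarray(on_probs, dtype=float)
        if on_probs.ndim != 2:
            raise ValueError("on_probs must be 2-D (2**n rows, n columns)")
        rows, n = on_probs.shape
        if rows != 2**n:
            raise ValueError(f"on_probs has {rows} rows for {n} units; expected {2**n}")
        if np.any(on_probs < -PROB_ATOL) or np.any(on_probs > 1 + PROB_ATOL):
            raise ValueError("probabilities must lie in [0, 1]")
        self.on_probs = np.clip(on_probs, 0.0, 1.0)
        self.n_units = n

    # -- basic views -------------------------------------------------------
    @property
    def unit_tables(self) -> list[np.ndarray]:
        """Per-unit ON-probability columns (views)."""
        return [self.on_probs[:, i] for i in range(self.n_units)]

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        return (
            isinstance(other, SystemTPM)
            and self.n_units == other.n_units
            and np.allclose(self.on_probs, other.on_probs, atol=PROB_ATOL)
        )

    def __repr__(self) -> str:
        return f"SystemTPM(n_units={self.n_units})"

    def is_deterministic(self) -> bool:
        return bool(np.all((self.on_probs == 0) | (self.on_probs == 1)))

    # -- conditioning helpers ---------------------------------------------
    def condition_mask(self, units: Sequence[int], state: Sequence[int]) -> np.ndarray:
        """Boolean mask over previous-state rows matching ``state`` on ``units``."""
        bits = all_states(self.n_units)
        mask = np.ones(2**self.n_units, dtype=bool)
        for u, b in zip(units, state):
            mask &= bits[:, u] == int(b)
        return mask

    def unit_on_given(self, units: Sequence[int], state: Sequence[int], unit: int) -> float:
        """Mean ON-probability of ``unit`` over previous states consistent with
        ``units = state``, the marginalized inputs being uniform (Eq. of the
        single-unit effect repertoire)."""
        mask = self.condition_mask(units, state)
        return float(self.on_probs[mask, unit].mean())

    def units_on_given(self, units: Sequence[int], state: Sequence[int],
                       outputs: Sequence[int]) -> np.ndarray:
        mask = self.condition_mask(units, state)
        return self.on_probs[np.ix_(mask, np.asarray(outputs, dtype=int))].mean(axis=0)

    def joint_tpm(self) -> np.ndarray:
        """Dense state-by-state matrix implied by conditional independence."""
        n = self.n_units
        bits = all_states(n)  # (2^n, n) next-state bits
        # P[s, s'] = prod_i p_i(s)^{bit_i(s')} (1-p_i(s))^{1-bit_i(s')}
        p = self.on_probs[:, None, :]  # (2^n, 1, n)
        b = bits[None, :, :]  # (1, 2^n, n)
        return np.prod(np.where(b == 1, p, 1.0 - p), axis=2)


def _validate_subset(tpm: SystemTPM, units: Sequence[int], what: str) -> tuple[int, ...]:
    units = tuple(int(u) for u in units)
    if any(u < 0 or u >= tpm.n_units for u in units):
        raise IndexError(f"{what} units {units} out of range for {tpm.n_units}-unit system")
    if len(set(units)) != len(units):
        raise ValueError(f"{what} units must be distinct: {units}")
    return units


@dataclass(frozen=True)
class Mechanism:
    """A subset of units with its state inherited from the system state."""

    units: tuple[int, ...]
    state: tuple[int, ...]

    def __post_init__(self):
        units = tuple(int(u) for u in self.units)
        state = tuple(int(b) for b in self.state)
        if len(units) != len(state):
            raise ValueError("mechanism state length must equal number of units")
        order = np.argsort(units)
        object.__setattr__(self, "units", tuple(units[i] for i in order))
        object.__setattr__(self, "state", tuple(state[i] for i in order))

    @classmethod
    def from_system_state(cls, units: Iterable[int], system_state: Sequence[int]) -> "Mechanism":
        units = sorted(int(u) for u in units)
        return cls(tuple(units), tuple(int(system_state[u]) for u in units))

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class Purview:
    """A subset of units whose states a mechanism constrains; optionally in a state."""

    units: tuple[int, ...]
    state: tuple[int, ...] | None = None

    def __post_init__(self):
        units = tuple(int(u) for u in self.units)
        order = np.argsort(units)
        object.__setattr__(self, "units", tuple(units[i] for i in order))
        if self.state is not None:
            state = tuple(int(b) for b in self.state)
            if len(state) != len(units):
                raise ValueError("purview state length must equal number of units")
            object.__setattr__(self, "state", tuple(state[i] for i in order))

    def __len__(self) -> int:
        return len(self.units)

    def unit_states(self) -> frozenset[tuple[int, int]]:
        if self.state is None:
            raise ValueError("purview has no state")
        return frozenset(zip(self.units, self.state))


@dataclass
class Repertoire:
    """Probability distribution over the states of a purview.

    ``probs[z]`` is the probability of the purview state with little-endian
    index ``z`` relative to the (sorted) purview units.  ``defined`` is False
    for the flagged "undefined cause" result (no purview state can produce
    the mechanism state); then ``probs`` is None and callers treat φc = 0.
    """

    purview: Purview
    probs: np.ndarray | None
    defined: bool = True

    def __post_init__(self):
        if self.defined:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != (2 ** len(self.purview),):
                raise ValueError("repertoire length must be 2**|Z|")
            total = self.probs.sum()
            if not np.isclose(total, 1.0, atol=PROB_ATOL):
                raise ValueError(f"repertoire does not sum to 1 (sum={total})")

    def prob(self, state: Sequence[int]) -> float:
        return float(self.probs[state_index(self.purview.units, state)])


def _product_distribution(p_on: Sequence[float]) -> np.ndarray:
    """Joint over purview states from independent per-unit ON-probabilities."""
    dist = np.ones(1)
    for p in p_on:
        dist = np.concatenate([dist * (1.0 - p), dist * p])
    return dist


# ---------------------------------------------------------------------------
# effect side
# ---------------------------------------------------------------------------

def effect_repertoire_single(tpm: SystemTPM, m: Mechanism, unit: int) -> Repertoire:
    """Single-unit effect repertoire: uniform average over the states of the
    units outside the mechanism of the unit's ON-probability given (m, w)."""
    _validate_subset(tpm, m.units, "mechanism")
    if not (0 <= int(unit) < tpm.n_units):
        raise IndexError(f"unit {unit} out of range")
    p = tpm.unit_on_given(m.units, m.state, int(unit))
    return Repertoire(Purview((int(unit),)), np.array([1.0 - p, p]))


def effect_repertoire(tpm: SystemTPM, m: Mechanism, Z: Purview) -> Repertoire:
    """Effect repertoire of purview ``Z``: product of single-unit repertoires."""
    _validate_subset(tpm, m.units, "mechanism")
    zunits = _validate_subset(tpm, Z.units, "purview")
    if not zunits:
        raise ValueError("purview must be non-empty")
    p_on = tpm.units_on_given(m.units, m.state, zunits)
    return Repertoire(Purview(zunits), _product_distribution(p_on))


def unconstrained_effect(tpm: SystemTPM, Z: Purview, M: Sequence[int]) -> Repertoire:
    """Uniform average of the effect repertoire over all states of ``M``."""
    munits = _validate_subset(tpm, M, "mechanism")
    zunits = _validate_subset(tpm, Z.units, "purview")
    if not zunits:
        raise ValueError("purview must be non-empty")
    k = len(munits)
    bits = all_states(tpm.n_units)
    if k:
        midx = bits[:, list(munits)].astype(np.int64) @ (1 << np.arange(k, dtype=np.int64))
    else:
        midx = np.zeros(2**tpm.n_units, dtype=np.int64)
    counts = np.bincount(midx, minlength=2**k).astype(float)
    # per-unit mean ON-probability for every mechanism state at once
    per_unit = np.empty((2**k, len(zunits)))
    for j, u in enumerate(zunits):
        per_unit[:, j] = np.bincount(midx, weights=tpm.on_probs[:, u], minlength=2**k) / counts
    acc = np.zeros(2 ** len(zunits))
    for ms in range(2**k):
        acc += _product_distribution(per_unit[ms])
    return Repertoire(Purview(zunits), acc / 2**k)


# ---------------------------------------------------------------------------
# cause side
# ---------------------------------------------------------------------------

def cause_likelihoods(tpm: SystemTPM, m: Mechanism, zunits: Sequence[int]) -> np.ndarray:
    """Per-mechanism-unit likelihood table ``L[j, z] = p(m_j | Z=z)`` with the
    non-purview inputs at t-1 causally marginalized (uniform average)."""
    n = tpm.n_units
    bits = all_states(n)
    k = len(zunits)
    zidx = bits[:, list(zunits)].astype(np.int64) @ (1 << np.arange(k, dtype=np.int64))
    counts = np.bincount(zidx, minlength=2**k).astype(float)
    L = np.empty((len(m.units), 2**k))
    for j, (u, b) in enumerate(zip(m.units, m.state)):
        w = tpm.on_probs[:, u] if b == 1 else 1.0 - tpm.on_probs[:, u]
        L[j] = np.bincount(zidx, weights=w, minlength=2**k) / counts
    return L


def cause_repertoire(tpm: SystemTPM, m: Mechanism, Z: Purview) -> Repertoire:
    """Backward repertoire over ``Z``: product of per-mechanism-unit
    likelihoods of the mechanism state, normalized over purview states.

    Returns a flagged undefined repertoire when the mechanism state has zero
    likelihood under every purview state; callers treat φc = 0.
    """
    _validate_subset(tpm, m.units, "mechanism")
    zunits = _validate_subset(tpm, Z.units, "purview")
    if not zunits:
        raise ValueError("purview must be non-empty")
    if not m.units:
        return Repertoire(Purview(zunits), np.full(2 ** len(zunits), 2.0 ** -len(zunits)))
    L = cause_likelihoods(tpm, m, zunits)
    joint = L.prod(axis=0)
    total = joint.sum()
    if total <= 0.0:
        return Repertoire(Purview(zunits), None, defined=False)
    return Repertoire(Purview(zunits), joint / total)


def unconstrained_cause(tpm: SystemTPM, Z: Purview, M: Sequence[int]) -> Repertoire:
    """Average of the cause repertoire over all mechanism states of ``M``
    (states with undefined repertoires are skipped and the average renormalized)."""
    munits = _validate_subset(tpm, M, "mechanism")
    zunits = _validate_subset(tpm, Z.units, "purview")
    acc = np.zeros(2 ** len(zunits))
    n_def = 0
    bits = all_states(len(munits))
    for ms in range(2 ** len(munits)):
        rep = cause_repertoire(tpm, Mechanism(munits, tuple(bits[ms])), Purview(zunits))
        if rep.defined:
            acc += rep.probs
            n_def += 1
    if n_def == 0:
        return Repertoire(Purview(zunits), None, defined=False)
    return Repertoire(Purview(zunits), acc / n_def)
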