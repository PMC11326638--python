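"""TPM families used in the numerical experiments.

All families are expressed in the state-by-node form (per-unit ON
probabilities, little-endian state indexing):

``copy_system``
    every unit copies its own previous state;
``threshold_system``
    the high-selectivity family: unit *i* is ON at ``t+1`` iff its own bit
    is ON **and** at least ``K`` units in total are ON at ``t``.  In the
    all-ON state every size-``K`` mechanism then specifies itself with
    probability 1, while every remaining TPM entry is 0, which maximizes
    the integrated effect information attainable under that constraint.
    At ``K = 1`` the family reduces to the copy system and at ``K = N`` to
    ``N``-input AND gates.  The defining selectivity property is verified
    computationally at construction time;
``random_deterministic``
    0/1 entries, each ON with a per-run probability drawn uniformly;
``random_stochastic``
    entries drawn independently from Uniform(0, 1);
``hamming74_system``
    7 units; each state maps with probability 1 to the nearest codeword of
    the (7, 4) Hamming code (a perfect code: the map is well defined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tpm import Mechanism, Purview, SystemTPM, all_states, effect_repertoire
from itertools import combinations

__all__ = [
    "ConstructionSpec",
    "copy_system",
    "threshold_system",
    "random_deterministic",
    "random_stochastic",
    "hamming74_system",
    "build",
]


@dataclass(frozen=True)
class ConstructionSpec:
    """Declarative description of a constructed system (recorded in outputs)."""

    family: str
    n_units: int
    k: int | None = None
    seed: int | None = None
    evaluation_state: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.family not in ("copy", "threshold", "random_deterministic",
                               "random_stochastic", "hamming74"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "threshold" and not (self.k and 1 <= self.k <= self.n_units):
            raise ValueError("threshold family requires 1 <= K <= N")
        if self.family == "hamming74" and self.n_units != 7:
            raise ValueError("hamming74 requires N = 7")

    @property
    def state(self) -> tuple[int, ...]:
        # evaluation defaults to the optimal (all-ON) state
        return self.evaluation_state or (1,) * self.n_units


def copy_system(n: int) -> SystemTPM:
    """Each unit's next state equals its own current state with probability 1."""
    if n < 1:
        raise ValueError("need at least one unit")
    return SystemTPM(all_states(n).astype(float))


def threshold_system(n: int, k: int, verify: bool = True) -> SystemTPM:
    """High-selectivity construction: unit ON iff self ON and >= k units ON.

    With ``verify=True`` (default) the defining property is checked: in the
    all-ON state, every size-``k`` mechanism's effect repertoire over itself
    is a point mass (selectivity 1).
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    bits = all_states(n)
    weight = bits.sum(axis=1)
    on = (bits == 1) & (weight >= k)[:, None]
    tpm = SystemTPM(on.astype(float))
    if verify:
        state = (1,) * k
        for units in combinations(range(n), k):
            m = Mechanism(units, state)
            rep = effect_repertoire(tpm, m, Purview(units))
            if not np.isclose(rep.probs.max(), 1.0, atol=1e-9):
                raise RuntimeError(
                    f"construction postcondition failed: mechanism {units} "
                    f"does not specify itself with probability 1"
                )
    return tpm


def random_deterministic(n: int, seed: int | None = None) -> SystemTPM:
    """Deterministic TPM with random 0/1 entries; the probability of a 1 is
    itself drawn once per run from Uniform(0, 1)."""
    rng = np.random.default_rng(seed)
    q = rng.uniform()
    return SystemTPM((rng.uniform(size=(2**n, n)) < q).astype(float))


def random_stochastic(n: int, seed: int | None = None) -> SystemTPM:
    """Each unit-table entry drawn independently from Uniform(0, 1)."""
    rng = np.random.default_rng(seed)
    return SystemTPM(rng.uniform(size=(2**n, n)))


def _hamming74_codewords() -> np.ndarray:
    """The 16 codewords, little-endian bit order (unit i = bit position i+1
    of the standard parity-check matrix whose column j is binary j)."""
    # parity check H: columns are 1..7 in binary (3 rows)
    H = np.array([[(j >> r) & 1 for j in range(1, 8)] for r in range(3)], dtype=np.int8)
    states = all_states(7)
    syndromes = (H @ states.T) % 2
    return states[np.flatnonzero(~syndromes.any(axis=0))]


def hamming74_system() -> SystemTPM:
    """Seven units; every state decodes to its nearest (7,4) codeword."""
    states = all_states(7)
    codewords = _hamming74_codewords()
    dist = (states[:, None, :] != codewords[None, :, :]).sum(axis=2)
    nearest = dist.argmin(axis=1)
    assert (dist[np.arange(128), nearest] <= 1).all()  # perfect code
    return SystemTPM(codewords[nearest].astype(float))


def build(spec: ConstructionSpec) -> SystemTPM:
    """Construct the TPM described by ``spec``."""
    if spec.family == "copy":
        return copy_system(spec.n_units)
    if spec.family == "threshold":
        return threshold_system(spec.n_units, spec.k)
    if spec.family == "random_deterministic":
        return random_deterministic(spec.n_units, spec.seed)
    if spec.family == "random_stochastic":
        return random_stochastic(spec.n_units, spec.seed)
    return hamming74_system()
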