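"""Numerical experiments: sweeps over system sizes, mechanism sizes and
TPM families, with seed bookkeeping and machine-readable outputs.

The heavy quantity is the sum of mechanism integrated information over all
2^N - 1 mechanisms.  For the constructed families that are invariant under
unit permutations (copy, threshold in the all-ON state) one representative
mechanism per size suffices and the sum is Σ_k C(N,k)·φ(size-k), which the
sweep functions exploit via ``use_symmetry``.

Every sweep returns a plain :class:`pandas.DataFrame`; ``write_sweep``
serializes it with a JSON manifest embedding the full configuration and
seeds so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import bounds as _bounds
from .constructions import (
    copy_system,
    hamming74_system,
    random_deterministic,
    random_stochastic,
    threshold_system,
)
from .phi import MechanismPhi, mechanism_phi
from .relations import sum_relations_decomposition
from .tpm import Mechanism, SystemTPM
from itertools import combinations

__all__ = [
    "SweepConfig",
    "sum_mechanism_phi",
    "system_distinctions",
    "system_relation_sum",
    "fig1_sweep",
    "fig2_sweep",
    "fig3_fig4_sweep",
    "write_sweep",
    "load_config",
]


@dataclass
class SweepConfig:
    """Configuration of a family sweep (fully recorded in every output)."""

    families: list[str] = field(default_factory=lambda: [
        "high_selectivity", "random_deterministic", "random_stochastic"])
    n_range: list[int] = field(default_factory=lambda: [2, 3])
    n_seeds: int = 100
    base_seed: int = 0
    evaluation_state: str = "all-on"
    purview_space: str | None = "self"
    scheme: str = "full"
    measure: str = "positive-part"
    include_relations: bool = False

    def seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_seeds)]


def load_config(path) -> SweepConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return SweepConfig(**data)


def _mechanisms(n: int, state: Sequence[int]) -> Iterable[Mechanism]:
    for r in range(1, n + 1):
        for units in combinations(range(n), r):
            yield Mechanism.from_system_state(units, state)


def sum_mechanism_phi(tpm: SystemTPM, state: Sequence[int], side: str = "both",
                      purview_space="self", scheme: str = "full",
                      use_symmetry: bool = False) -> float:
    """Σ over all mechanisms of φe, φc or φ = min(φe, φc).

    ``use_symmetry`` evaluates one mechanism per size and multiplies by
    C(N, k); valid only for TPM/state pairs invariant under unit
    permutations (the constructed families in the all-ON state).
    """
    n = tpm.n_units
    total = 0.0
    if use_symmetry:
        for k in range(1, n + 1):
            m = Mechanism.from_system_state(range(k), state)
            total += comb(n, k) * _phi_of(tpm, m, side, purview_space, scheme)
    else:
        for m in _mechanisms(n, state):
            total += _phi_of(tpm, m, side, purview_space, scheme)
    return total


def _phi_of(tpm, m, side, purview_space, scheme) -> float:
    space = [m.units] if purview_space == "self" else purview_space
    res = mechanism_phi(tpm, m, purview_space=space, scheme=scheme)
    if side == "effect":
        return res.effect.phi if res.effect else 0.0
    if side == "cause":
        return res.cause.phi if res.cause else 0.0
    return res.phi


def system_distinctions(tpm: SystemTPM, state: Sequence[int],
                        purview_space=None, scheme: str = "full"
                        ) -> list[MechanismPhi]:
    """Full purview search for every mechanism of the system in ``state``."""
    return [mechanism_phi(tpm, m, purview_space=purview_space, scheme=scheme)
            for m in _mechanisms(tpm.n_units, state)]


def system_relation_sum(tpm: SystemTPM, state: Sequence[int],
                        purview_space=None, scheme: str = "full"):
    """Σ φr over all subsets of the system's distinctions (exact
    decomposition) together with Σ φ_d."""
    ds = [r.distinction for r in system_distinctions(tpm, state, purview_space, scheme)
          if r.irreducible]
    sum_phi_d = sum(d.phi for d in ds)
    return sum_relations_decomposition(ds) if ds else 0.0, sum_phi_d, len(ds)


# ---------------------------------------------------------------------------
# figure sweeps
# ---------------------------------------------------------------------------

def fig1_sweep(N_list: Sequence[int], K_range: Sequence[int] | None = None
               ) -> pd.DataFrame:
    """φe*(N, K) of a size-K mechanism over itself vs the K² bound, and the
    size-weighted count C(N,K)·φe*(N,K)."""
    rows = []
    for N in N_list:
        for K in (K_range or range(1, N + 1)):
            if K > N:
                continue
            star = _bounds.phi_e_star(N, K)
            rows.append({"N": N, "K": K, "phi_e_star": star,
                         "pair_bound": K * K,
                         "count": comb(N, K),
                         "weighted": comb(N, K) * star})
    return pd.DataFrame(rows)


def fig2_sweep(N_list: Sequence[int], include_cause: bool = False) -> pd.DataFrame:
    """For each N and K: Σφe over all mechanisms of threshold_system(N, K)
    in the all-ON state (reflexive purviews), the numerical bound
    Σ_K C(N,K)·φe*(K) and optionally Σφ = Σ min(φe, φc)."""
    rows = []
    for N in N_list:
        bound = _bounds.numerical_sum_bound(N)
        state = (1,) * N
        for K in range(1, N + 1):
            tpm = threshold_system(N, K, verify=False)
            row = {"N": N, "K": K,
                   "sum_phi_e": sum_mechanism_phi(tpm, state, side="effect",
                                                  use_symmetry=True),
                   "numerical_bound": bound}
            if include_cause:
                row["sum_phi"] = sum_mechanism_phi(tpm, state, side="both",
                                                   use_symmetry=True)
            rows.append(row)
    return pd.DataFrame(rows)


def _family_tpms(family: str, n: int, config: SweepConfig):
    if family == "high_selectivity":
        return [("K=%d" % k, threshold_system(n, k, verify=False), True)
                for k in range(1, n + 1)]
    if family == "copy":
        return [("copy", copy_system(n), True)]
    if family == "random_deterministic":
        return [("seed=%d" % s, random_deterministic(n, s), False)
                for s in config.seeds()]
    if family == "random_stochastic":
        return [("seed=%d" % s, random_stochastic(n, s), False)
                for s in config.seeds()]
    if family == "hamming74":
        return [("hamming74", hamming74_system(), False)] if n == 7 else []
    raise ValueError(f"unknown family {family!r}")


def fig3_fig4_sweep(config: SweepConfig) -> pd.DataFrame:
    """Best achievable Σφ_d per family per N (the random families report the
    maximum over their seeds) and, when ``include_relations``, Σφ_r of the
    best variant's distinction set."""
    rows = []
    for n in config.n_range:
        state = (1,) * n
        for family in config.families:
            best = None
            for label, tpm, symmetric in _family_tpms(family, n, config):
                total = sum_mechanism_phi(
                    tpm, state, side="both", purview_space=config.purview_space,
                    scheme=config.scheme, use_symmetry=symmetric)
                if best is None or total > best[1]:
                    best = (label, total, tpm)
            if best is None:
                continue
            row = {"N": n, "family": family, "variant": best[0],
                   "sum_phi_d": best[1]}
            if config.include_relations:
                # distinctions for relations always use the full purview search
                rel, _, n_dist = system_relation_sum(best[2], state,
                                                    scheme=config.scheme)
                row.update({"sum_phi_r": float(rel), "n_distinctions": n_dist})
            rows.append(row)
    return pd.DataFrame(rows)


def write_sweep(df: pd.DataFrame, out_csv, config: SweepConfig | dict | None = None
                ) -> None:
    """CSV plus a JSON manifest embedding the configuration (deterministic
    byte output for identical inputs)."""
    out_csv = Path(out_csv)
    df.to_csv(out_csv, index=False, float_format="%.12g")
    manifest = {
        "columns": list(df.columns),
        "rows": len(df),
        "config": asdict(config) if isinstance(config, SweepConfig) else (config or {}),
    }
    out_csv.with_name(out_csv.name + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
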