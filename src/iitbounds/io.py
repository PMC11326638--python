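"""Plain-text TPM files.

Two dialects:

``state-by-node``
    ``2^N`` rows × ``N`` columns of per-unit ON-probabilities — the native
    representation;
``state-by-state``
    ``2^N × 2^N`` row-stochastic joint matrix, accepted on input only and
    factorized into unit tables; rows whose joint is not the product of its
    unit marginals (conditional independence violated) are rejected.

Row indices are little-endian (unit 0 = least significant bit).  A JSON
sidecar (``<file>.json``) records the dialect, the unit count and the
endianness; on read it is consulted when present, otherwise the dialect is
inferred from the matrix shape.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .tpm import PROB_ATOL, SystemTPM, all_states

__all__ = ["read_tpm", "write_tpm", "TPMFormatError"]

DIALECTS = ("state-by-node", "state-by-state")


class TPMFormatError(ValueError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_tpm(tpm: SystemTPM, path, dialect: str = "state-by-node") -> None:
    path = Path(path)
    if dialect == "state-by-node":
        mat = tpm.on_probs
    elif dialect == "state-by-state":
        mat = tpm.joint_tpm()
    else:
        raise TPMFormatError(f"unknown dialect {dialect!r}")
    np.savetxt(path, mat, delimiter=",", fmt="%.17g")
    _sidecar(path).write_text(json.dumps({
        "dialect": dialect,
        "n_units": tpm.n_units,
        "endianness": "little",
    }, indent=2))


def _factorize_state_by_state(mat: np.ndarray) -> np.ndarray:
    rows, cols = mat.shape
    if rows != cols:
        raise TPMFormatError("state-by-state matrix must be square")
    n = int(math.log2(rows))
    if 2**n != rows:
        raise TPMFormatError(f"dimension {rows} is not a power of two")
    sums = mat.sum(axis=1)
    bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=PROB_ATOL))
    if bad.size:
        raise TPMFormatError(f"row {bad[0]} is not stochastic (sum={sums[bad[0]]})")
    if np.any(mat < -PROB_ATOL):
        raise TPMFormatError("negative transition probabilities")
    bits = all_states(n)
    on = mat @ bits  # per-unit marginal ON-probabilities
    # reject joints that are not products of their unit marginals
    recon = np.prod(np.where(bits[None, :, :] == 1, on[:, None, :],
                             1.0 - on[:, None, :]), axis=2)
    err = np.abs(recon - mat).max(axis=1)
    bad = np.flatnonzero(err > PROB_ATOL)
    if bad.size:
        raise TPMFormatError(
            f"row {bad[0]} violates conditional independence "
            f"(max deviation {err[bad[0]]:.3g}); the joint is not a product "
            f"of unit marginals"
        )
    return on


def read_tpm(path, dialect: str | None = None) -> SystemTPM:
    path = Path(path)
    side = _sidecar(path)
    if dialect is None and side.exists():
        meta = json.loads(side.read_text())
        dialect = meta.get("dialect")
        if meta.get("endianness", "little") != "little":
            raise TPMFormatError("only little-endian TPM files are supported")
    try:
        mat = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise TPMFormatError(f"cannot parse {path}: {exc}") from exc
    if dialect is None:
        dialect = "state-by-state" if mat.shape[0] == mat.shape[1] else "state-by-node"
    if dialect == "state-by-node":
        rows, n = mat.shape
        if rows != 2**n:
            raise TPMFormatError(
                f"state-by-node matrix must be 2^N x N, got {rows} x {n}")
        if np.any(mat < -PROB_ATOL) or np.any(mat > 1 + PROB_ATOL):
            raise TPMFormatError("probabilities outside [0, 1]")
        return SystemTPM(mat)
    if dialect == "state-by-state":
        return SystemTPM(_factorize_state_by_state(mat))
    raise TPMFormatError(f"unknown dialect {dialect!r}")
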