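"""Fermion-to-qubit encodings: Jordan–Wigner and parity (with reduction).

Jordan–Wigner stores mode occupations directly in qubit states, with the
convention a^dag_p = (X_p - iY_p)/2 ⊗ Z-chain on qubits < p.  The parity
encoding stores cumulative occupation parities; with blocked spin ordering
the qubit at position n-1 carries the alpha-electron parity and the last
qubit the total parity, and both can be removed for operators that conserve
particle number and Sz (two-qubit reduction).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .fermion import (FermionOperator, spin_summed_excitation,
                      spin_summed_pair_excitation)
from .pauli import QubitOperator, identity_label

__all__ = ["Encoding", "jordan_wigner", "parity_map", "parity_map_reduced",
           "map_operator", "encode_occupations", "rdm_component_operators",
           "MappingError"]


class MappingError(ValueError):
    """Encoding preconditions violated (e.g. symmetry sector broken)."""


class Encoding(str, Enum):
    JW = "jw"
    PARITY_REDUCED = "parity_reduced"


def _label_with(n: int, assignments: dict[int, str]) -> str:
    chars = ["I"] * n
    for pos, ch in assignments.items():
        chars[pos] = ch
    return "".join(chars)


def _jw_ladder(mode: int, dagger: bool, n: int) -> QubitOperator:
    sign = -1j if dagger else 1j
    chain = {k: "Z" for k in range(mode)}
    x_term = _label_with(n, {**chain, mode: "X"})
    y_term = _label_with(n, {**chain, mode: "Y"})
    return QubitOperator(n, {x_term: 0.5, y_term: 0.5 * sign})


def _parity_ladder(mode: int, dagger: bool, n: int) -> QubitOperator:
    # a^dag_j = 1/2 (Z_{j-1} X_j -+ i Y_j) ⊗ X-chain on qubits > j
    sign = -1j if dagger else 1j
    chain = {k: "X" for k in range(mode + 1, n)}
    if mode > 0:
        zx = _label_with(n, {**chain, mode - 1: "Z", mode: "X"})
    else:
        zx = _label_with(n, {**chain, mode: "X"})
    y = _label_with(n, {**chain, mode: "Y"})
    return QubitOperator(n, {zx: 0.5, y: 0.5 * sign})


def _map_fermion(f: FermionOperator, ladder) -> QubitOperator:
    n = f.n_modes
    out = QubitOperator.zero(n)
    cache: dict[tuple[int, bool], QubitOperator] = {}
    for seq, coeff in f.terms.items():
        term = QubitOperator.identity(n, coeff)
        for mode, dag in seq:
            key = (mode, dag)
            if key not in cache:
                cache[key] = ladder(mode, dag, n)
            term = term * cache[key]
        out = out + term
    return out.simplify()


def jordan_wigner(f: FermionOperator) -> QubitOperator:
    """Jordan–Wigner image of a fermionic operator (one qubit per mode)."""
    return _map_fermion(f, _jw_ladder)


def parity_map(f: FermionOperator) -> QubitOperator:
    """Parity-encoding image (one qubit per mode, no reduction)."""
    return _map_fermion(f, _parity_ladder)


def parity_map_reduced(f: FermionOperator, n_elec: int, sz2: int) -> QubitOperator:
    """Parity image with the two symmetry qubits removed.

    Requires blocked spin ordering and an operator that conserves particle
    number and Sz; qubits n/2-1 (alpha parity) and n-1 (total parity) then
    act only as I or Z and are replaced by their sector eigenvalues
    (-1)^n_alpha and (-1)^n_elec.
    """
    full = parity_map(f)
    n = f.n_modes
    if n % 2 != 0:
        raise MappingError("blocked spin ordering needs an even mode count")
    pa, pt = n // 2 - 1, n - 1
    n_alpha = (n_elec + sz2) // 2
    za = (-1.0) ** n_alpha
    zt = (-1.0) ** n_elec
    out: dict[str, complex] = {}
    for lbl, c in full.terms.items():
        if lbl[pa] in ("X", "Y") or lbl[pt] in ("X", "Y"):
            raise MappingError(
                "operator does not conserve the (n_elec, sz) sector: "
                f"term {lbl} acts on a symmetry qubit")
        factor = (za if lbl[pa] == "Z" else 1.0) * (zt if lbl[pt] == "Z" else 1.0)
        red = "".join(ch for k, ch in enumerate(lbl) if k not in (pa, pt))
        out[red] = out.get(red, 0.0) + factor * c
    return QubitOperator(n - 2, out).simplify()


def map_operator(f: FermionOperator, encoding: Encoding,
                 n_elec: int | None = None, sz2: int = 0) -> QubitOperator:
    if encoding == Encoding.JW:
        return jordan_wigner(f)
    if encoding == Encoding.PARITY_REDUCED:
        if n_elec is None:
            raise MappingError("parity reduction needs the electron sector")
        return parity_map_reduced(f, n_elec, sz2)
    raise MappingError(f"unknown encoding {encoding!r}")


def encode_occupations(occ: np.ndarray, encoding: Encoding) -> np.ndarray:
    """Qubit bit values for a mode-occupation vector under an encoding."""
    occ = np.asarray(occ, dtype=int)
    if encoding == Encoding.JW:
        return occ.copy()
    if encoding == Encoding.PARITY_REDUCED:
        par = np.cumsum(occ) % 2
        n = occ.shape[0]
        keep = [j for j in range(n) if j not in (n // 2 - 1, n - 1)]
        return par[keep]
    raise MappingError(f"unknown encoding {encoding!r}")


def rdm_component_operators(n_orb: int, encoding: Encoding,
                            n_elec: int | None = None, sz2: int = 0):
    """Qubit images of the spin-summed RDM component operators.

    Returns ``(ops1, ops2)`` where ``ops1[(p, q)]`` is the image of E_pq and
    ``ops2[(p, q, r, s)]`` the image of e_pqrs = E_pq E_rs - delta_qr E_ps.
    Every index combination is measured independently, so a noisy 1-RDM
    estimate is genuinely asymmetric before the symmetrization step.
    """
    ops1 = {}
    for p in range(n_orb):
        for q in range(n_orb):
            ops1[(p, q)] = map_operator(
                spin_summed_excitation(p, q, n_orb), encoding, n_elec, sz2)
    ops2 = {}
    for p in range(n_orb):
        for q in range(n_orb):
            for r in range(n_orb):
                for s in range(n_orb):
                    ops2[(p, q, r, s)] = map_operator(
                        spin_summed_pair_excitation(p, q, r, s, n_orb),
                        encoding, n_elec, sz2)
    return ops1, ops2
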