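"""Exact active-space ground states by sector-projected diagonalization.

Serves both as the FCI driver inside CASSCF macro-iterations and as the
test oracle for the variational solvers.  The qubit Hamiltonian is
restricted to the basis states of a fixed (n_electrons, 2Sz) sector and
diagonalized densely; active spaces of up to ~6 orbitals are trivial.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .active_space import ActiveHamiltonian
from .fermion import to_spin_orbitals
from .mapping import Encoding, encode_occupations, map_operator
from .pauli import QubitOperator
from .rdm import RDMPair
from .statevector import Statevector

__all__ = ["SectorSpec", "sector_basis", "ground_state", "exact_rdms",
           "solve_active_hamiltonian"]


class SectorError(ValueError):
    pass


@dataclass(frozen=True)
class SectorSpec:
    """Particle-number / spin-projection sector of the active space."""

    n_electrons: int
    sz2: int = 0

    def __post_init__(self):
        if abs(self.sz2) > self.n_electrons \
                or (self.n_electrons - self.sz2) % 2 != 0:
            raise SectorError(f"invalid sector ({self.n_electrons}, {self.sz2})")

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.sz2) // 2

    @property
    def n_beta(self) -> int:
        return (self.n_electrons - self.sz2) // 2


def sector_basis(n_orb: int, sector: SectorSpec,
                 encoding: Encoding = Encoding.JW) -> np.ndarray:
    """Basis-state indices of the sector under the chosen encoding."""
    if sector.n_alpha > n_orb or sector.n_beta > n_orb:
        raise SectorError("sector does not fit in the active space")
    indices = []
    for occ_a in combinations(range(n_orb), sector.n_alpha):
        for occ_b in combinations(range(n_orb), sector.n_beta):
            occ = np.zeros(2 * n_orb, dtype=int)
            occ[list(occ_a)] = 1
            occ[[n_orb + b for b in occ_b]] = 1
            bits = encode_occupations(occ, encoding)
            indices.append(int(sum(int(b) << j for j, b in enumerate(bits))))
    out = np.array(sorted(set(indices)), dtype=np.int64)
    if out.size == 0:
        raise SectorError("empty sector")
    if out.size != len(indices):
        raise SectorError("encoding collapsed distinct sector states")
    return out


def _restricted_matrix(op: QubitOperator, basis: np.ndarray) -> np.ndarray:
    """Matrix of ``op`` restricted to the given basis-state indices."""
    pos = {int(b): k for k, b in enumerate(basis)}
    dim = basis.size
    H = np.zeros((dim, dim), dtype=complex)
    for lbl, c in op.terms.items():
        xmask = 0
        phasemask = 0
        ny = 0
        for j, ch in enumerate(lbl):
            if ch in ("X", "Y"):
                xmask |= 1 << j
            if ch in ("Z", "Y"):
                phasemask |= 1 << j
            if ch == "Y":
                ny += 1
        phase0 = c * (1j) ** ny
        for k, b in enumerate(basis):
            b = int(b)
            target = b ^ xmask
            kt = pos.get(target)
            if kt is None:
                continue
            sign = -1.0 if bin(b & phasemask).count("1") % 2 else 1.0
            H[kt, k] += phase0 * sign
    return H


def ground_state(h: QubitOperator, sector: SectorSpec, n_orb: int,
                 encoding: Encoding = Encoding.JW
                 ) -> tuple[float, Statevector]:
    """Lowest eigenvalue and eigenvector of ``h`` within a symmetry sector.

    The returned statevector is embedded in the full 2^n register of the
    encoding, so expectation values of any mapped operator can be taken.
    """
    basis = sector_basis(n_orb, sector, encoding)
    H = _restricted_matrix(h, basis)
    if np.max(np.abs(H - H.conj().T)) > 1e-9:
        raise ValueError("Hamiltonian is not Hermitian on the sector")
    evals, evecs = np.linalg.eigh(0.5 * (H + H.conj().T))
    vec = evecs[:, 0]
    amp = np.zeros(2 ** h.n_qubits, dtype=complex)
    amp[basis] = vec
    return float(evals[0]), Statevector(amp)


def exact_rdms(state: Statevector, n_orb: int,
               encoding: Encoding = Encoding.JW,
               sector: SectorSpec | None = None) -> RDMPair:
    """Spin-summed RDMs of a state via the mapped excitation operators."""
    from .mapping import rdm_component_operators
    n_elec = sector.n_electrons if sector is not None else None
    sz2 = sector.sz2 if sector is not None else 0
    ops1, ops2 = rdm_component_operators(n_orb, encoding, n_elec, sz2)
    dm1 = np.zeros((n_orb, n_orb))
    for (p, q), op in ops1.items():
        dm1[p, q] = np.real(state.expectation(op))
    dm2 = np.zeros((n_orb,) * 4)
    for (p, q, r, s), op in ops2.items():
        dm2[p, q, r, s] = np.real(state.expectation(op))
    n = sector.n_electrons if sector is not None \
        else int(round(np.trace(dm1)))
    return RDMPair(dm1=dm1, dm2=dm2, n_electrons=n)


def solve_active_hamiltonian(h_act: ActiveHamiltonian,
                             encoding: Encoding = Encoding.JW
                             ) -> tuple[float, Statevector, RDMPair]:
    """FCI driver: total energy, sector ground state and exact RDMs."""
    sector = SectorSpec(h_act.n_active_electrons, h_act.sz2)
    f = to_spin_orbitals(h_act)
    qubit_h = map_operator(f, encoding, sector.n_electrons, sector.sz2)
    energy, state = ground_state(qubit_h, sector, h_act.n_active_orbitals,
                                 encoding)
    rdms = exact_rdms(state, h_act.n_active_orbitals, encoding, sector)
    return energy, state, rdms
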