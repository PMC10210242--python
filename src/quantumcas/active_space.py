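"""Active-space selection and effective active-space Hamiltonians.

The electronic Hamiltonian restricted to a CAS(n_elec, n_orb) window is
characterized by an effective one-body matrix (bare one-electron integrals
dressed with the mean field of the doubly occupied inactive orbitals), the
bare two-electron integrals over active orbitals, and a core energy (nuclear
repulsion plus the inactive-space mean-field energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals import AOIntegrals
from .scf import SCFResult

__all__ = ["ActiveSpace", "ActiveHamiltonian", "select_active_space",
           "build_active_hamiltonian", "active_hamiltonian_from_mo"]


class ActiveSpaceError(ValueError):
    """Impossible electron bookkeeping or invalid orbital indices."""


@dataclass(frozen=True)
class ActiveSpace:
    """Partition of the MO space into inactive / active / virtual orbitals."""

    n_active_electrons: int
    active_indices: tuple[int, ...]
    inactive_indices: tuple[int, ...]
    virtual_indices: tuple[int, ...]
    sz2: int = 0     # 2*Sz of the active electrons

    def __post_init__(self):
        all_idx = (set(self.active_indices) | set(self.inactive_indices)
                   | set(self.virtual_indices))
        n = len(self.active_indices) + len(self.inactive_indices) \
            + len(self.virtual_indices)
        if len(all_idx) != n:
            raise ActiveSpaceError("orbital index sets overlap")
        if not 0 <= self.n_active_electrons <= 2 * len(self.active_indices):
            raise ActiveSpaceError(
                f"{self.n_active_electrons} electrons do not fit in "
                f"{len(self.active_indices)} active orbitals")
        if abs(self.sz2) > self.n_active_electrons \
                or (self.sz2 - self.n_active_electrons) % 2 != 0:
            raise ActiveSpaceError(f"sz2={self.sz2} inconsistent with "
                                   f"{self.n_active_electrons} electrons")

    @property
    def n_active_orbitals(self) -> int:
        return len(self.active_indices)

    @property
    def n_alpha(self) -> int:
        return (self.n_active_electrons + self.sz2) // 2

    @property
    def n_beta(self) -> int:
        return (self.n_active_electrons - self.sz2) // 2

    def n_qubits(self, two_qubit_reduction: bool = False) -> int:
        n = 2 * self.n_active_orbitals
        return n - 2 if two_qubit_reduction else n


def select_active_space(scf: SCFResult, n_elec: int,
                        indices: list[int]) -> ActiveSpace:
    """Build an ActiveSpace from explicit MO indices.

    Inactive orbitals are the lowest-energy occupied MOs not in ``indices``
    such that inactive + active electrons add up to the molecular electron
    count; everything else is virtual.  Indices need not be contiguous.
    """
    n_mo = scf.n_mo
    indices = tuple(sorted(indices))
    if any(i < 0 or i >= n_mo for i in indices):
        raise ActiveSpaceError(f"active indices out of range 0..{n_mo - 1}")
    n_total = scf.n_alpha + scf.n_beta
    n_inactive_elec = n_total - n_elec
    if n_inactive_elec < 0 or n_inactive_elec % 2 != 0:
        raise ActiveSpaceError(
            f"cannot place {n_total} electrons with {n_elec} active: "
            f"inactive count {n_inactive_elec} must be even and >= 0")
    n_inactive = n_inactive_elec // 2
    pool = [i for i in range(n_mo) if i not in indices]
    inactive = tuple(pool[:n_inactive])
    if len(inactive) < n_inactive:
        raise ActiveSpaceError("not enough non-active orbitals to hold the "
                               "inactive electrons")
    virtual = tuple(pool[n_inactive:])
    sz2 = scf.n_alpha - scf.n_beta  # excess alpha electrons live in the CAS
    if abs(sz2) > n_elec:
        raise ActiveSpaceError("open-shell electrons exceed the active count")
    return ActiveSpace(n_active_electrons=n_elec, active_indices=indices,
                       inactive_indices=inactive, virtual_indices=virtual,
                       sz2=sz2)


def frontier_active_space(scf: SCFResult, n_elec: int, n_orb: int) -> ActiveSpace:
    """HOMO-centred CAS(n_elec, n_orb) window around the Fermi level."""
    n_docc_in_cas = (n_elec - (scf.n_alpha - scf.n_beta)) // 2
    n_somo = scf.n_alpha - scf.n_beta
    first = scf.n_beta - n_docc_in_cas
    indices = list(range(first, first + n_orb))
    if n_docc_in_cas + n_somo > n_orb:
        raise ActiveSpaceError(f"CAS({n_elec},{n_orb}) cannot hold the "
                               "occupied frontier orbitals")
    return select_active_space(scf, n_elec, indices)


@dataclass
class ActiveHamiltonian:
    """Second-quantized Hamiltonian data for one active space.

    ``h_eff`` is the one-body matrix including the inactive mean field,
    ``g_act`` the two-body integrals over active MOs in chemist notation
    (pq|rs), and ``e_core`` the inactive + nuclear energy, so that
    E_total = e_core + <H_active>.
    """

    h_eff: np.ndarray
    g_act: np.ndarray
    e_core: float
    n_active_electrons: int
    sz2: int = 0

    @property
    def n_active_orbitals(self) -> int:
        return self.h_eff.shape[0]

    def energy_from_rdms(self, dm1: np.ndarray, dm2: np.ndarray) -> float:
        """Total energy from spin-summed RDMs (chemist-ordered dm2)."""
        return float(self.e_core + np.sum(self.h_eff * dm1)
                     + 0.5 * np.einsum("pqrs,pqrs->", self.g_act, dm2))

    def rotate(self, U: np.ndarray) -> "ActiveHamiltonian":
        """Transform to a new active-orbital basis phi'_p = sum_q U_qp phi_q."""
        h = U.T @ self.h_eff @ U
        g = np.einsum("pqrs,pi,qj,rk,sl->ijkl", self.g_act, U, U, U, U,
                      optimize=True)
        return ActiveHamiltonian(h, g, self.e_core, self.n_active_electrons,
                                 self.sz2)


def build_active_hamiltonian(ints: AOIntegrals, scf: SCFResult,
                             act: ActiveSpace) -> ActiveHamiltonian:
    """Effective Hamiltonian over the active MOs of a converged reference."""
    return active_hamiltonian_from_mo(ints, scf.mo_coefficients, act)


def active_hamiltonian_from_mo(ints: AOIntegrals, C: np.ndarray,
                               act: ActiveSpace) -> ActiveHamiltonian:
    """Same as :func:`build_active_hamiltonian` for explicit MO coefficients."""
    Ci = C[:, list(act.inactive_indices)]
    Ca = C[:, list(act.active_indices)]
    h_ao = ints.core_hamiltonian
    Dcore = 2.0 * Ci @ Ci.T
    J = np.einsum("pqrs,rs->pq", ints.eri, Dcore, optimize=True)
    K = np.einsum("prqs,rs->pq", ints.eri, Dcore, optimize=True)
    F_core_ao = h_ao + J - 0.5 * K
    h_eff = Ca.T @ F_core_ao @ Ca
    e_core = ints.nuclear_repulsion \
        + 0.5 * np.sum(Dcore * (h_ao + F_core_ao))
    g_act = np.einsum("pqrs,pi,qj,rk,sl->ijkl", ints.eri, Ca, Ca, Ca, Ca,
                      optimize=True)
    h_eff = 0.5 * (h_eff + h_eff.T)
    return ActiveHamiltonian(h_eff=h_eff, g_act=g_act, e_core=float(e_core),
                             n_active_electrons=act.n_active_electrons,
                             sz2=act.sz2)
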