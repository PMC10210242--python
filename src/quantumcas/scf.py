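"""Restricted Hartree–Fock (RHF) and restricted open-shell HF (ROHF).

Roothaan iterations with DIIS acceleration.  Closed-shell systems use RHF;
systems with unpaired electrons (e.g. doublet radicals) use ROHF with a
Roothaan effective Fock operator, so the spatial orbitals stay restricted
and the downstream active-space machinery sees a single MO set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .geometry import Geometry
from .integrals import AOIntegrals

__all__ = ["SCFResult", "SCFError", "run_hf"]


class SCFError(RuntimeError):
    def __init__(self, msg: str, last_energy: float | None = None):
        super().__init__(msg)
        self.last_energy = last_energy


@dataclass
class SCFResult:
    """Converged mean-field reference.

    ``mo_coefficients`` columns are orthonormal under the AO overlap metric;
    orbitals are sorted by ascending orbital energy (ties broken by original
    index), and ``occupations`` holds total (alpha+beta) occupation numbers.
    """

    mo_coefficients: np.ndarray
    mo_energies: np.ndarray
    hf_energy: float
    occupations: np.ndarray
    converged: bool
    n_alpha: int
    n_beta: int
    n_iterations: int = 0

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]

    @property
    def n_occupied(self) -> int:
        """Number of (at least singly) occupied MOs."""
        return self.n_alpha

    @property
    def homo_index(self) -> int:
        return self.n_alpha - 1

    @property
    def lumo_index(self) -> int:
        return self.n_alpha


def _coulomb_exchange(eri: np.ndarray, dm: np.ndarray):
    J = np.einsum("pqrs,rs->pq", eri, dm, optimize=True)
    K = np.einsum("prqs,rs->pq", eri, dm, optimize=True)
    return J, K


class _DIIS:
    def __init__(self, max_vec: int = 8):
        self.errs: list[np.ndarray] = []
        self.focks: list[np.ndarray] = []
        self.max_vec = max_vec

    def update(self, F: np.ndarray, err: np.ndarray) -> np.ndarray:
        self.errs.append(err.ravel().copy())
        self.focks.append(F.copy())
        if len(self.errs) > self.max_vec:
            self.errs.pop(0)
            self.focks.pop(0)
        n = len(self.errs)
        if n < 2:
            return F
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.errs[i] @ self.errs[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return F
        return sum(ci * Fi for ci, Fi in zip(c, self.focks))


def run_hf(ints: AOIntegrals, geometry: Geometry,
           max_cycles: int = 200, conv_energy: float = 1e-11,
           conv_residual: float = 1e-8) -> SCFResult:
    """Solve the (RO)HF equations; RHF when all electrons are paired.

    The convergence flag requires both an energy change below
    ``conv_energy`` (default well under 1e-10 Ha) and a DIIS residual norm
    below ``conv_residual``.
    """
    na, nb = geometry.n_alpha, geometry.n_beta
    if na + nb != geometry.n_electrons:
        raise SCFError("electron bookkeeping failed")
    h = ints.core_hamiltonian
    S = ints.overlap
    X = _orthogonalizer(S)
    enuc = ints.nuclear_repulsion

    # core-Hamiltonian guess
    C = _solve_fock(h, X)
    e_old = 0.0
    diis = _DIIS()
    converged = False
    restricted = (na == nb)
    ncyc = 0
    for ncyc in range(1, max_cycles + 1):
        Ca = C[:, :na]
        Cb = C[:, :nb]
        Da = Ca @ Ca.T
        Db = Cb @ Cb.T
        D = Da + Db
        J, _ = _coulomb_exchange(ints.eri, D)
        _, Ka = _coulomb_exchange(ints.eri, Da)
        if restricted:
            Kb = Ka
        else:
            _, Kb = _coulomb_exchange(ints.eri, Db)
        Fa = h + J - Ka
        Fb = h + J - Kb
        energy = 0.5 * (np.sum(Da * (h + Fa)) + np.sum(Db * (h + Fb))) + enuc

        if restricted:
            F_eff = Fa
        else:
            F_eff = _rohf_effective_fock(Fa, Fb, C, S, na, nb)

        err = F_eff @ D @ S - S @ D @ F_eff
        err = X.T @ err @ X
        resid = np.linalg.norm(err)
        de = abs(energy - e_old)
        if de < conv_energy and resid < conv_residual and ncyc > 1:
            converged = True
            break
        F_use = diis.update(F_eff, err)
        C = _solve_fock(F_use, X)
        e_old = energy

    if not converged:
        raise SCFError(f"SCF did not converge in {max_cycles} cycles "
                       f"(last E = {energy:.10f})", last_energy=energy)

    # final canonical orbitals/energies from the effective Fock
    mo_e, C = _solve_fock(F_eff, X, return_energies=True)
    order = np.argsort(mo_e, kind="stable")
    mo_e = mo_e[order]
    C = C[:, order]
    occ = np.zeros(C.shape[1])
    occ[:nb] += 1.0
    occ[:na] += 1.0
    return SCFResult(mo_coefficients=C, mo_energies=mo_e, hf_energy=float(energy),
                     occupations=occ, converged=converged,
                     n_alpha=na, n_beta=nb, n_iterations=ncyc)


def _orthogonalizer(S: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(S)
    if evals.min() < 1e-10:
        raise SCFError("overlap matrix is (numerically) singular")
    return evecs @ np.diag(evals ** -0.5) @ evecs.T


def _solve_fock(F: np.ndarray, X: np.ndarray, return_energies: bool = False):
    e, Cp = np.linalg.eigh(X.T @ F @ X)
    C = X @ Cp
    if return_energies:
        return e, C
    return C


def _rohf_effective_fock(Fa, Fb, C, S, na, nb):
    """Roothaan single effective Fock operator in the AO basis.

    In the basis of the current MOs the blocks are: closed-open -> Fb,
    open-virtual -> Fa, all remaining -> (Fa+Fb)/2.
    """
    Fa_mo = C.T @ Fa @ C
    Fb_mo = C.T @ Fb @ C
    n = C.shape[1]
    Feff = 0.5 * (Fa_mo + Fb_mo)
    closed = slice(0, nb)
    open_ = slice(nb, na)
    virt = slice(na, n)
    Feff[closed, open_] = Fb_mo[closed, open_]
    Feff[open_, closed] = Fb_mo[open_, closed]
    Feff[open_, virt] = Fa_mo[open_, virt]
    Feff[virt, open_] = Fa_mo[virt, open_]
    # back to AO basis: F_ao = S C Feff C^T S
    return S @ C @ Feff @ C.T @ S
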