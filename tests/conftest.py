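"""Shared fixtures: molecular systems, Hamiltonians, and a Fock-space oracle.

The Fock-space oracle builds fermionic operator matrices directly from
occupation-number-vector ladder algebra (explicit sign bookkeeping), fully
independent of the Pauli-algebra mapping path it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from quantumcas.active_space import (build_active_hamiltonian,
                                     frontier_active_space,
                                     select_active_space)
from quantumcas.geometry import Geometry, bundled_geometry
from quantumcas.integrals import compute_ao_integrals
from quantumcas.scf import run_hf


# ---------------------------------------------------------------------------
# independent dense Fock-space oracle
# ---------------------------------------------------------------------------

def ladder_matrix(mode: int, dagger: bool, n_modes: int) -> np.ndarray:
    """Creation/annihilation matrix in the occupation-number basis."""
    dim = 2 ** n_modes
    M = np.zeros((dim, dim))
    for b in range(dim):
        occupied = (b >> mode) & 1
        sign = (-1) ** bin(b & ((1 << mode) - 1)).count("1")
        if dagger and not occupied:
            M[b | (1 << mode), b] = sign
        if not dagger and occupied:
            M[b ^ (1 << mode), b] = sign
    return M


def fermion_to_dense(fermion_op) -> np.ndarray:
    """Dense matrix of a FermionOperator via the ladder-matrix oracle."""
    dim = 2 ** fermion_op.n_modes
    H = np.zeros((dim, dim), dtype=complex)
    for seq, coeff in fermion_op.terms.items():
        M = np.eye(dim, dtype=complex)
        for mode, dag in seq:
            M = M @ ladder_matrix(mode, dag, fermion_op.n_modes)
        H += coeff * M
    return H


@pytest.fixture(scope="session")
def fock_oracle():
    return fermion_to_dense


# ---------------------------------------------------------------------------
# molecular systems (computed once per session)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def h2_system():
    geom = bundled_geometry("h2_0.74")
    ints = compute_ao_integrals(geom, "sto-3g")
    scf = run_hf(ints, geom)
    act = select_active_space(scf, 2, [0, 1])
    ham = build_active_hamiltonian(ints, scf, act)
    return {"geom": geom, "ints": ints, "scf": scf, "act": act, "ham": ham}


@pytest.fixture(scope="session")
def water_system():
    geom = bundled_geometry("water_synthetic")
    ints = compute_ao_integrals(geom, "sto-3g")
    scf = run_hf(ints, geom)
    return {"geom": geom, "ints": ints, "scf": scf}


@pytest.fixture(scope="session")
def water_cas22(water_system):
    scf = water_system["scf"]
    act = frontier_active_space(scf, 2, 2)
    ham = build_active_hamiltonian(water_system["ints"], scf, act)
    return {**water_system, "act": act, "ham": ham}


@pytest.fixture(scope="session")
def co_system():
    geom = bundled_geometry("co_1.54")
    ints = compute_ao_integrals(geom, "cc-pvdz")
    scf = run_hf(ints, geom)
    act = frontier_active_space(scf, 2, 2)
    ham = build_active_hamiltonian(ints, scf, act)
    return {"geom": geom, "ints": ints, "scf": scf, "act": act, "ham": ham}


@pytest.fixture(scope="session")
def co_casscf_fci(co_system):
    from quantumcas.casscf import Driver, run_casscf
    state, trace = run_casscf(co_system["ints"],
                              co_system["scf"].mo_coefficients,
                              co_system["act"], Driver.FCI)
    return state, trace


@pytest.fixture(scope="session")
def co_casscf_uccsd(co_system):
    from quantumcas.casscf import Driver, run_casscf
    state, trace = run_casscf(co_system["ints"],
                              co_system["scf"].mo_coefficients,
                              co_system["act"], Driver.UCCSD_VQE)
    return state, trace


@pytest.fixture()
def oh_radical():
    geom = Geometry([("O", 0.0, 0.0, 0.0), ("H", 0.0, 0.0, 0.97)],
                    spin_multiplicity=2)
    ints = compute_ao_integrals(geom, "sto-3g")
    return geom, ints
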