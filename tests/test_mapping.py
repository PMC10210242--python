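"""Fermion-to-qubit mappings and Pauli-string algebra.

The independent check is the dense Fock-space oracle from conftest, which
builds operator matrices from occupation-number ladder algebra without any
Pauli machinery.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quantumcas.active_space import ActiveHamiltonian
from quantumcas.exact import SectorSpec, sector_basis, ground_state
from quantumcas.fermion import (FermionOperator, spin_summed_excitation,
                                to_spin_orbitals)
from quantumcas.fixtures import random_hamiltonian
from quantumcas.mapping import (Encoding, MappingError, jordan_wigner,
                                map_operator, parity_map,
                                parity_map_reduced, rdm_component_operators)
from quantumcas.pauli import QubitOperator
from quantumcas.statevector import Statevector
from quantumcas.ansatz import prepare_reference


class TestJordanWigner:
    def test_number_operator_identity(self):
        f = FermionOperator(1, {((0, True), (0, False)): 1.0})
        q = jordan_wigner(f)
        assert q.terms == {"I": pytest.approx(0.5), "Z": pytest.approx(-0.5)}

    def test_number_operator_locality(self):
        f = FermionOperator(2, {((1, True), (1, False)): 1.0})
        q = jordan_wigner(f)
        assert q.terms == {"II": pytest.approx(0.5), "IZ": pytest.approx(-0.5)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_fock_oracle(self, seed, fock_oracle):
        ham = random_hamiltonian(2, 2, seed)
        f = to_spin_orbitals(ham)
        assert np.max(np.abs(fock_oracle(f) - jordan_wigner(f).to_dense())) \
            < 1e-12

    def test_hermitian_input_gives_real_coefficients(self):
        ham = random_hamiltonian(3, 2, 5)
        q = jordan_wigner(to_spin_orbitals(ham))
        assert q.is_hermitian(tol=1e-10)

    def test_spin_orbital_count(self):
        ham = random_hamiltonian(4, 4, 0)
        f = to_spin_orbitals(ham)
        assert f.n_modes == 8          # "SOs = 2 x MOs"
        assert jordan_wigner(f).n_qubits == 8


class TestParityReduced:
    @pytest.mark.parametrize("seed,n_orb,n_elec,sz2", [
        (0, 2, 2, 0), (1, 2, 2, 0), (2, 3, 3, 1), (3, 3, 4, 0),
    ])
    def test_sector_spectrum_matches_jw(self, seed, n_orb, n_elec, sz2):
        ham = random_hamiltonian(n_orb, n_elec, seed)
        ham.sz2 = sz2
        f = to_spin_orbitals(ham)
        sector = SectorSpec(n_elec, sz2)
        jw = jordan_wigner(f)
        red = parity_map_reduced(f, n_elec, sz2)
        assert red.n_qubits == 2 * n_orb - 2
        e_jw = np.linalg.eigvalsh(_restrict(jw, n_orb, sector, Encoding.JW))
        e_red = np.linalg.eigvalsh(_restrict(red, n_orb, sector,
                                             Encoding.PARITY_REDUCED))
        assert np.max(np.abs(e_jw - e_red)) < 1e-10

    def test_parity_full_spectrum_preserved(self):
        ham = random_hamiltonian(2, 2, 9)
        f = to_spin_orbitals(ham)
        e1 = np.linalg.eigvalsh(jordan_wigner(f).to_dense())
        e2 = np.linalg.eigvalsh(parity_map(f).to_dense())
        assert np.max(np.abs(e1 - e2)) < 1e-10

    def test_total_number_operator_reduces_to_constant(self):
        n_orb = 2
        f = FermionOperator(2 * n_orb)
        for m in range(2 * n_orb):
            f.add_term(((m, True), (m, False)), 1.0)
        red = parity_map_reduced(f, 2, 0)
        # N is fixed in the sector: only Z-type terms survive, and the
        # identity coefficient carries the electron count contribution
        assert red.is_hermitian()

    def test_symmetry_violation_detected(self):
        f = FermionOperator(4, {((0, True),): 1.0})   # breaks particle number
        with pytest.raises(MappingError):
            parity_map_reduced(f, 2, 0)


def _restrict(op, n_orb, sector, encoding):
    basis = sector_basis(n_orb, sector, encoding)
    dense = op.to_dense()
    return dense[np.ix_(basis, basis)]


class TestSimplify:
    def test_cancellation(self):
        q = QubitOperator(1, {"X": 1.0}) + QubitOperator(1, {"X": -1.0})
        assert q.simplify().n_terms == 0

    def test_threshold(self):
        assert QubitOperator(1, {"Z": 1e-14}).simplify(1e-12).n_terms == 0

    def test_zero_tolerance_preserves_matrix(self):
        ham = random_hamiltonian(2, 2, 3)
        q = jordan_wigner(to_spin_orbitals(ham))
        assert np.allclose(q.to_dense(), q.simplify(0.0).to_dense())

    @given(st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_term_count_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["".join(rng.choice(list("IXYZ"), 3)) for _ in range(5)]
        q = QubitOperator(3, {l: rng.normal() for l in labels})
        assert q.simplify(1e-3).n_terms <= q.n_terms

    def test_serialization_round_trip(self):
        ham = random_hamiltonian(2, 2, 4)
        q = jordan_wigner(to_spin_orbitals(ham))
        again = QubitOperator.from_text(q.to_text())
        assert np.allclose(q.to_dense(), again.to_dense())


class TestPauliAlgebra:
    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_product_matches_dense_matrices(self, seed):
        rng = np.random.default_rng(seed)
        la = "".join(rng.choice(list("IXYZ"), 2))
        lb = "".join(rng.choice(list("IXYZ"), 2))
        qa, qb = QubitOperator.from_label(la), QubitOperator.from_label(lb)
        assert np.allclose((qa * qb).to_dense(),
                           qa.to_dense() @ qb.to_dense())

    def test_apply_matches_dense(self):
        rng = np.random.default_rng(1)
        ham = random_hamiltonian(2, 2, 1)
        q = jordan_wigner(to_spin_orbitals(ham))
        v = rng.normal(size=16) + 1j * rng.normal(size=16)
        assert np.allclose(q.apply(v), q.to_dense() @ v)


class TestRDMComponents:
    def test_e_pp_counts_doubly_occupied_orbital(self):
        ref = prepare_reference(2, 1, 1, Encoding.JW)    # |1100> blocked
        op = jordan_wigner(spin_summed_excitation(0, 0, 2))
        assert np.real(ref.expectation(op)) == pytest.approx(2.0)

    def test_total_number_trace(self):
        n_orb, n_elec = 3, 4
        ham = random_hamiltonian(n_orb, n_elec, 11)
        from quantumcas.exact import solve_active_hamiltonian
        _, state, _ = solve_active_hamiltonian(ham)
        total = QubitOperator.zero(2 * n_orb)
        for p in range(n_orb):
            total = total + jordan_wigner(
                spin_summed_excitation(p, p, n_orb))
        assert np.real(state.expectation(total)) == pytest.approx(n_elec,
                                                                  abs=1e-9)

    def test_pair_operator_on_hf_state(self, fock_oracle):
        from quantumcas.fermion import spin_summed_pair_excitation
        ref = prepare_reference(2, 1, 1, Encoding.JW)
        op = jordan_wigner(spin_summed_pair_excitation(0, 0, 0, 0, 2))
        assert np.real(ref.expectation(op)) == pytest.approx(2.0)
        # cross-check through the independent Fock-space oracle
        dense = fock_oracle(spin_summed_pair_excitation(0, 0, 0, 0, 2))
        v = ref.amplitudes
        assert np.real(v.conj() @ dense @ v) == pytest.approx(2.0)

    def test_component_maps_share_encoding(self):
        ops1, ops2 = rdm_component_operators(2, Encoding.PARITY_REDUCED,
                                             n_elec=2, sz2=0)
        assert all(op.n_qubits == 2 for op in ops1.values())
        assert all(op.n_qubits == 2 for op in ops2.values())
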