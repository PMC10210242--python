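"""RDM post-processing pipeline: normalization, symmetrization,
canonicalization and 2-RDM constraints."""

import numpy as np
import pytest

from quantumcas.exact import solve_active_hamiltonian
from quantumcas.fixtures import random_hamiltonian
from quantumcas.rdm import (NaturalOrbitalTransform, RDMError, RDMPair,
                            canonicalize, constrain_dm2, normalize_dm1,
                            process_rdms, symmetrize_dm1)


def _hf_pair(n=2):
    dm1 = np.diag([2.0] + [0.0] * (n - 1))
    dm2 = (np.einsum("pq,rs->pqrs", dm1, dm1)
           - 0.5 * np.einsum("ps,qr->pqrs", dm1, dm1))
    return RDMPair(dm1=dm1, dm2=dm2, n_electrons=2)


class TestNormalize:
    def test_rescales_trace(self):
        r = RDMPair(np.diag([1.9, 0.0]), np.zeros((2,) * 4), 2)
        out = normalize_dm1(r)
        assert np.allclose(out.dm1, np.diag([2.0, 0.0]))
        assert out.normalized

    def test_idempotent_on_normalized_input(self):
        out = normalize_dm1(normalize_dm1(_hf_pair()))
        assert np.allclose(out.dm1, np.diag([2.0, 0.0]))

    def test_nonpositive_trace_raises(self):
        r = RDMPair(np.diag([-1.0, 0.0]), np.zeros((2,) * 4), 2)
        with pytest.raises(RDMError):
            normalize_dm1(r)

    def test_noisy_trace_exact_after_normalization(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            dm1 = np.diag([2.0, 0.0]) + rng.normal(scale=0.05, size=(2, 2))
            out = normalize_dm1(RDMPair(dm1, np.zeros((2,) * 4), 2))
            assert np.trace(out.dm1) == pytest.approx(2.0, abs=1e-12)


class TestSymmetrize:
    def test_arithmetic_mean(self):
        r = RDMPair(np.array([[2.0, 0.1], [0.3, 0.0]]), np.zeros((2,) * 4), 2)
        out = symmetrize_dm1(r)
        assert np.allclose(out.dm1, [[2.0, 0.2], [0.2, 0.0]])

    def test_symmetric_input_unchanged_and_trace_kept(self):
        r = _hf_pair()
        out = symmetrize_dm1(r)
        assert np.allclose(out.dm1, r.dm1)
        assert np.trace(out.dm1) == pytest.approx(2.0)

    def test_frobenius_projection_property(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        out = symmetrize_dm1(RDMPair(A, np.zeros((3,) * 4), 2))
        d_star = np.linalg.norm(A - out.dm1)
        for _ in range(25):
            S = rng.normal(size=(3, 3))
            S = 0.5 * (S + S.T)
            assert np.linalg.norm(A - S) >= d_star - 1e-12


class TestCanonicalize:
    def test_diagonal_descending_input_gives_identity_rotation(self):
        r = _hf_pair()
        out, tr = canonicalize(r)
        assert np.allclose(tr.rotation, np.eye(2))
        assert np.allclose(tr.occupations, [2.0, 0.0])

    def test_occupations_descending_and_rotation_orthogonal(self):
        ham = random_hamiltonian(3, 4, 2)
        _, _, rdms = solve_active_hamiltonian(ham)
        out, tr = canonicalize(symmetrize_dm1(rdms))
        assert np.all(np.diff(tr.occupations) <= 1e-12)
        assert np.allclose(tr.rotation @ tr.rotation.T, np.eye(3),
                           atol=1e-10)
        assert np.allclose(out.dm1, np.diag(tr.occupations), atol=1e-10)

    def test_occupation_sum_is_electron_count(self):
        ham = random_hamiltonian(3, 3, 8)
        _, _, rdms = solve_active_hamiltonian(ham)
        _, tr = canonicalize(symmetrize_dm1(rdms))
        assert tr.occupations.sum() == pytest.approx(3.0, abs=1e-9)

    def test_requires_symmetric_input(self):
        r = RDMPair(np.array([[2.0, 0.5], [0.0, 0.0]]), np.zeros((2,) * 4), 2)
        with pytest.raises(RDMError):
            canonicalize(r)


class TestConstrainDm2:
    def test_hf_state_is_fixed_point(self):
        r = _hf_pair()
        out = constrain_dm2(r)
        assert np.allclose(out.dm2, r.dm2, atol=1e-12)

    def test_exact_fci_rdms_unchanged(self):
        ham = random_hamiltonian(2, 2, 6)
        _, _, rdms = solve_active_hamiltonian(ham)
        out = constrain_dm2(rdms)
        assert np.allclose(out.dm2, rdms.dm2, atol=1e-10)

    def test_perturbed_dm2_partial_trace_restored(self):
        ham = random_hamiltonian(2, 2, 7)
        _, _, rdms = solve_active_hamiltonian(ham)
        rng = np.random.default_rng(1)
        noisy = rdms.copy()
        noisy.dm2 = noisy.dm2 + rng.normal(scale=0.02, size=noisy.dm2.shape)
        out = constrain_dm2(noisy)
        N = rdms.n_electrons
        ptrace = np.einsum("pqrr->pq", out.dm2)
        assert np.allclose(ptrace, (N - 1) * out.dm1, atol=1e-10)
        full = float(np.einsum("ppqq->", out.dm2))
        assert full == pytest.approx(N * (N - 1), abs=1e-10)


class TestPipeline:
    def test_idempotence(self):
        ham = random_hamiltonian(3, 4, 12)
        _, _, rdms = solve_active_hamiltonian(ham)
        rng = np.random.default_rng(5)
        noisy = rdms.copy()
        noisy.dm1 = noisy.dm1 + rng.normal(scale=0.03, size=noisy.dm1.shape)
        noisy.dm2 = noisy.dm2 + rng.normal(scale=0.03, size=noisy.dm2.shape)
        once, _ = process_rdms(noisy, canonical=True)
        twice, _ = process_rdms(once, canonical=True)
        assert np.allclose(once.dm1, twice.dm1, atol=1e-12)
        assert np.allclose(once.dm2, twice.dm2, atol=1e-12)

    def test_trace_conserved_and_occupations_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            dm1 = np.diag([2.0, 0.0]) + rng.normal(scale=0.15, size=(2, 2))
            dm2 = rng.normal(scale=0.1, size=(2,) * 4)
            out, _ = process_rdms(RDMPair(dm1, dm2, 2), canonical=True)
            occ = out.occupations()
            assert np.trace(out.dm1) == pytest.approx(2.0, abs=1e-9)
            assert np.all(occ >= -1e-12) and np.all(occ <= 2 + 1e-12)

    def test_noncanonical_mode_skips_only_diagonalization(self):
        ham = random_hamiltonian(2, 2, 13)
        _, _, rdms = solve_active_hamiltonian(ham)
        out, transform = process_rdms(rdms, canonical=False)
        assert transform is None
        assert out.normalized and out.symmetrized and not out.canonicalized

    def test_exact_rdms_pass_through_unchanged(self):
        # noiseless FCI densities already satisfy every constraint
        ham = random_hamiltonian(2, 2, 14)
        _, _, rdms = solve_active_hamiltonian(ham)
        out, _ = process_rdms(rdms, canonical=False)
        assert np.allclose(out.dm1, rdms.dm1, atol=1e-10)
        assert np.allclose(out.dm2, rdms.dm2, atol=1e-10)
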