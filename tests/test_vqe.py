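"""VQE engine: expectations, shot sampling, optimizers, RDM measurement."""

import numpy as np
import pytest

from quantumcas.ansatz import (AnsatzKind, apply_hea, apply_uccsd, hea_spec,
                               prepare_reference, uccsd_spec)
from quantumcas.exact import SectorSpec, solve_active_hamiltonian
from quantumcas.fermion import to_spin_orbitals
from quantumcas.fixtures import random_hamiltonian, stretched_diatomic
from quantumcas.mapping import Encoding, jordan_wigner, map_operator
from quantumcas.noise import IDEAL, NoiseSpec
from quantumcas.pauli import QubitOperator
from quantumcas.statevector import Statevector
from quantumcas.vqe import (OptimizerSpec, VQEDriver, expectation,
                            measure_rdms, sampled_expectation, spsa_minimize,
                            vqe_minimize)


class TestExpectation:
    def test_z_on_zero_state(self):
        assert expectation(Statevector.zero_state(1),
                           QubitOperator.from_label("Z")) == pytest.approx(1.0)

    def test_identity_on_any_state(self):
        rng = np.random.default_rng(0)
        state = Statevector(rng.normal(size=8) + 1j * rng.normal(size=8),
                            normalize=True)
        assert expectation(state, QubitOperator.identity(3)) \
            == pytest.approx(1.0)

    def test_matches_dense_quadratic_form(self):
        rng = np.random.default_rng(5)
        ham = random_hamiltonian(2, 2, 5)
        q = jordan_wigner(to_spin_orbitals(ham))
        state = Statevector(rng.normal(size=16) + 1j * rng.normal(size=16),
                            normalize=True)
        dense = q.to_dense()
        assert expectation(state, q) == pytest.approx(
            float(np.real(state.amplitudes.conj() @ dense
                          @ state.amplitudes)), abs=1e-12)

    def test_non_hermitian_rejected(self):
        with pytest.raises(ValueError):
            expectation(Statevector.zero_state(1),
                        QubitOperator(1, {"X": 1j}))


class TestSampledExpectation:
    def test_z_on_zero_state_deterministic(self):
        v = sampled_expectation(Statevector.zero_state(1),
                                QubitOperator.from_label("Z"), shots=64)
        assert v == 1.0

    def test_x_on_zero_state_shot_noise_scaling(self):
        # <X> = 0 with binomial variance 1/shots: std halves per 4x shots
        state = Statevector.zero_state(1)
        op = QubitOperator.from_label("X")
        stds = []
        for shots in (100, 400, 1600):
            vals = [sampled_expectation(state, op, shots, seed=s)
                    for s in range(200)]
            assert abs(np.mean(vals)) < 5.0 / np.sqrt(shots * 200)
            stds.append(np.std(vals))
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.3)
        assert stds[1] / stds[2] == pytest.approx(2.0, rel=0.3)

    def test_full_depolarizing_kills_traceless_observable(self):
        state = Statevector.zero_state(2)
        noise = NoiseSpec(depolarizing_1q=1.0)
        vals = [sampled_expectation(state, QubitOperator.from_label("ZZ"),
                                    2000, noise, seed=s) for s in range(20)]
        assert abs(np.mean(vals)) < 0.05

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        state = Statevector(rng.normal(size=4), normalize=True)
        op = QubitOperator(2, {"XZ": 0.7, "YI": -0.2})
        a = sampled_expectation(state, op, 500, seed=11)
        b = sampled_expectation(state, op, 500, seed=11)
        assert a == b


class TestUCCSD:
    def test_zero_parameters_is_reference(self, h2_system):
        spec = uccsd_spec(2, 1, 1)
        ref = prepare_reference(2, 1, 1)
        out = apply_uccsd(ref, np.zeros(spec.parameter_count), spec)
        assert np.allclose(out.amplitudes, ref.amplitudes)

    def test_norm_preserved_and_variational(self, h2_system):
        ham = h2_system["ham"]
        e_fci, _, _ = solve_active_hamiltonian(ham)
        q = map_operator(to_spin_orbitals(ham), Encoding.JW, 2, 0)
        spec = uccsd_spec(2, 1, 1)
        rng = np.random.default_rng(8)
        for _ in range(5):
            theta = rng.normal(scale=0.5, size=spec.parameter_count)
            state = apply_uccsd(prepare_reference(2, 1, 1), theta, spec)
            assert state.norm() == pytest.approx(1.0, abs=1e-10)
            assert expectation(state, q) >= e_fci - 1e-9

    def test_reference_energy_equals_hf(self, co_system):
        # the aufbau reference on canonical orbitals reproduces HF
        ham = co_system["ham"]
        q = map_operator(to_spin_orbitals(ham), Encoding.JW, 2, 0)
        ref = prepare_reference(2, 1, 1)
        assert expectation(ref, q) == pytest.approx(
            co_system["scf"].hf_energy, abs=1e-9)

    def test_open_shell_reference_occupation(self):
        # doublet CAS(3,3): 2 alpha + 1 beta
        ref = prepare_reference(3, 2, 1, Encoding.JW)
        idx = int(np.argmax(np.abs(ref.amplitudes)))
        assert [int(b) for b in f"{idx:06b}"[::-1]] == [1, 1, 0, 1, 0, 0]


class TestMinimize:
    def test_constant_hamiltonian(self):
        spec = hea_spec(2, 1)
        h = QubitOperator.identity(2, 0.75)
        res = vqe_minimize(h, spec, OptimizerSpec(maxiter=5), seed=0)
        assert res.energy == pytest.approx(0.75)

    def test_uccsd_exact_for_two_orbitals(self, h2_system):
        ham = h2_system["ham"]
        e_fci, _, _ = solve_active_hamiltonian(ham)
        res, _, _ = VQEDriver(ansatz=AnsatzKind.UCCSD).solve(ham)
        assert res.energy == pytest.approx(e_fci, abs=1e-9)

    def test_variational_bound_on_fixtures(self):
        for seed in (1, 2):
            ham = random_hamiltonian(2, 2, seed)
            e_fci, _, _ = solve_active_hamiltonian(ham)
            res, _, _ = VQEDriver(ansatz=AnsatzKind.UCCSD).solve(ham)
            assert res.energy >= e_fci - 1e-9
            assert res.energy == pytest.approx(e_fci, abs=1e-9)

    def test_result_no_worse_than_initial_point(self, h2_system):
        ham = h2_system["ham"]
        q = map_operator(to_spin_orbitals(ham), Encoding.JW, 2, 0)
        spec = uccsd_spec(2, 1, 1)
        e_ref = expectation(apply_uccsd(prepare_reference(2, 1, 1),
                                        np.zeros(spec.parameter_count), spec),
                            q)
        res = vqe_minimize(q, spec, OptimizerSpec(), seed=0)
        assert res.energy <= e_ref + 1e-12

    def test_spsa_minimizes_quadratic(self):
        rng = np.random.default_rng(0)
        opt = OptimizerSpec(method="spsa", spsa_iterations=200)
        x, trace, n_eval = spsa_minimize(
            lambda v: float(np.sum((v - 1.0) ** 2)),
            np.zeros(3), opt, rng)
        assert np.allclose(x, 1.0, atol=0.2)
        assert n_eval >= 2 * 200


class TestHEA:
    def test_zero_parameters_give_vacuum(self):
        spec = hea_spec(2, 1)
        state = apply_hea(np.zeros(spec.parameter_count), spec)
        assert abs(state.amplitudes[0]) == pytest.approx(1.0)

    def test_hea_reaches_fci_on_co_cas22(self, co_system):
        # the 2-qubit hardware-efficient circuit matches the UCCSD/FCI
        # accuracy for the strongly correlated stretched-CO active space
        ham = co_system["ham"]
        e_fci, _, _ = solve_active_hamiltonian(ham)
        driver = VQEDriver(ansatz=AnsatzKind.HEA,
                           encoding=Encoding.PARITY_REDUCED, seed=3)
        res, _, rdms = driver.solve(ham)
        assert res.energy == pytest.approx(e_fci, abs=1e-6)
        assert res.energy >= e_fci - 1e-9


class TestMeasureRDMs:
    def test_hf_reference_density(self):
        state = prepare_reference(2, 1, 1, Encoding.JW)
        rdms = measure_rdms(state, 2, Encoding.JW, SectorSpec(2, 0))
        assert np.allclose(rdms.dm1, np.diag([2.0, 0.0]), atol=1e-12)

    def test_particle_number_conserved_noiseless(self):
        ham = random_hamiltonian(2, 2, 19)
        _, state, _ = solve_active_hamiltonian(ham)
        rdms = measure_rdms(state, 2, Encoding.JW, SectorSpec(2, 0))
        assert np.trace(rdms.dm1) == pytest.approx(2.0, abs=1e-9)

    def test_sampled_rdms_converge_to_exact(self):
        ham = stretched_diatomic(1.5)
        _, state, exact = solve_active_hamiltonian(ham)
        sampled = measure_rdms(state, 2, Encoding.JW, SectorSpec(2, 0),
                               shots=4000, seed=2)
        assert np.allclose(sampled.dm1, exact.dm1, atol=0.1)
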