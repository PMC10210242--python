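"""Orbital optimization: gradients, rotations and the CASSCF macro-loop."""

import numpy as np
import pytest
import scipy.linalg as sla

from quantumcas.active_space import active_hamiltonian_from_mo
from quantumcas.casscf import (ConvergenceCriteria, Driver,
                               _kappa_matrix, _pair_list, energy_fixed_rdms,
                               generalized_fock, orbital_gradient,
                               rotate_orbitals, run_casscf, warm_start)
from quantumcas.exact import solve_active_hamiltonian
from quantumcas.rdm import RDMPair


def _hf_rdms(n_act, n_docc):
    dm1 = np.diag([2.0] * n_docc + [0.0] * (n_act - n_docc))
    dm2 = (np.einsum("pq,rs->pqrs", dm1, dm1)
           - 0.5 * np.einsum("ps,qr->pqrs", dm1, dm1))
    return dm1, dm2


class TestGradient:
    def test_brillouin_condition_at_hf(self, water_cas22):
        # with mean-field RDMs at the converged HF orbitals the orbital
        # gradient must vanish (Brillouin theorem)
        ints, scf, act = (water_cas22["ints"], water_cas22["scf"],
                          water_cas22["act"])
        dm1, dm2 = _hf_rdms(2, 1)
        F = generalized_fock(ints, scf.mo_coefficients, act, dm1, dm2)
        g = orbital_gradient(F, act)
        assert np.max(np.abs(g)) < 1e-6

    def test_matches_finite_differences(self, water_cas22):
        ints, scf, act = (water_cas22["ints"], water_cas22["scf"],
                          water_cas22["act"])
        ham = water_cas22["ham"]
        _, _, rdms = solve_active_hamiltonian(ham)
        C = scf.mo_coefficients
        pairs = _pair_list(act, C.shape[1])
        F = generalized_fock(ints, C, act, rdms.dm1, rdms.dm2)
        G = 2.0 * (F - F.T)
        rng = np.random.default_rng(4)
        h = 1e-6
        for k in rng.choice(len(pairs), size=8, replace=False):
            dk = np.zeros(len(pairs))
            dk[k] = h
            K = _kappa_matrix(dk, pairs, C.shape[1])
            ep = energy_fixed_rdms(ints, C @ sla.expm(-K), act,
                                   rdms.dm1, rdms.dm2)
            em = energy_fixed_rdms(ints, C @ sla.expm(K), act,
                                   rdms.dm1, rdms.dm2)
            p, q = pairs[k]
            assert (ep - em) / (2 * h) == pytest.approx(G[p, q], abs=1e-6)

    def test_symmetric_fock_gives_zero_gradient(self, water_cas22):
        act = water_cas22["act"]
        n = water_cas22["scf"].n_mo
        F = np.eye(n) * 0.3
        assert np.allclose(orbital_gradient(F, act), 0.0)

    def test_energy_consistency_fixed_rdms(self, co_system):
        # the frozen-RDM energy at the reference orbitals equals the CI energy
        ints, scf, act = (co_system["ints"], co_system["scf"],
                          co_system["act"])
        e, _, rdms = solve_active_hamiltonian(co_system["ham"])
        assert energy_fixed_rdms(ints, scf.mo_coefficients, act,
                                 rdms.dm1, rdms.dm2) == pytest.approx(
            e, abs=1e-10)


class TestRotation:
    def test_zero_step_is_identity(self, water_cas22):
        C = water_cas22["scf"].mo_coefficients
        act = water_cas22["act"]
        nk = len(_pair_list(act, C.shape[1]))
        assert np.allclose(rotate_orbitals(C, np.zeros(nk), act), C)

    def test_orthonormality_preserved(self, water_cas22):
        C = water_cas22["scf"].mo_coefficients
        S = water_cas22["ints"].overlap
        act = water_cas22["act"]
        rng = np.random.default_rng(0)
        nk = len(_pair_list(act, C.shape[1]))
        C2 = rotate_orbitals(C, rng.normal(scale=0.3, size=nk), act)
        assert np.allclose(C2.T @ S @ C2, np.eye(C.shape[1]), atol=1e-10)

    def test_descent_along_negative_gradient(self, water_cas22):
        ints, scf, act = (water_cas22["ints"], water_cas22["scf"],
                          water_cas22["act"])
        _, _, rdms = solve_active_hamiltonian(water_cas22["ham"])
        C = scf.mo_coefficients
        F = generalized_fock(ints, C, act, rdms.dm1, rdms.dm2)
        g = orbital_gradient(F, act)
        assert np.linalg.norm(g) > 1e-4      # non-stationary fixture
        e0 = energy_fixed_rdms(ints, C, act, rdms.dm1, rdms.dm2)
        C1 = rotate_orbitals(C, -1e-3 * g, act)
        e1 = energy_fixed_rdms(ints, C1, act, rdms.dm1, rdms.dm2)
        assert e1 < e0


class TestMacroLoop:
    def test_water_cas22_converges_monotonically(self, water_cas22):
        state, trace = run_casscf(water_cas22["ints"],
                                  water_cas22["scf"].mo_coefficients,
                                  water_cas22["act"], Driver.FCI)
        assert state.converged
        assert np.linalg.norm(
            orbital_gradient(
                generalized_fock(water_cas22["ints"], state.mo_coefficients,
                                 state.active_space, state.rdms.dm1,
                                 state.rdms.dm2),
                state.active_space)) < 1e-5
        energies = np.array(trace.energies)
        assert np.all(np.diff(energies) < 1e-9)

    def test_canonical_and_noncanonical_agree_noiseless(self, water_cas22):
        kw = dict(act=water_cas22["act"], driver=Driver.FCI)
        s1, _ = run_casscf(water_cas22["ints"],
                           water_cas22["scf"].mo_coefficients,
                           options={"canonical": True}, **kw)
        s2, _ = run_casscf(water_cas22["ints"],
                           water_cas22["scf"].mo_coefficients,
                           options={"canonical": False}, **kw)
        assert s1.energy == pytest.approx(s2.energy, abs=1e-8)

    def test_final_energy_invariant_to_initial_active_rotation(
            self, water_cas22):
        ints, scf, act = (water_cas22["ints"], water_cas22["scf"],
                          water_cas22["act"])
        s1, _ = run_casscf(ints, scf.mo_coefficients, act, Driver.FCI)
        rng = np.random.default_rng(2)
        A = rng.normal(size=(2, 2))
        C = scf.mo_coefficients.copy()
        C[:, list(act.active_indices)] = \
            C[:, list(act.active_indices)] @ sla.expm(A - A.T)
        s2, _ = run_casscf(ints, C, act, Driver.FCI)
        assert s2.energy == pytest.approx(s1.energy, abs=1e-8)

    def test_warm_start_from_converged_state_is_fixed_point(
            self, water_cas22):
        ints, act = water_cas22["ints"], water_cas22["act"]
        s1, _ = run_casscf(ints, water_cas22["scf"].mo_coefficients, act,
                           Driver.FCI)
        C0 = warm_start(s1, act)
        s2, trace2 = run_casscf(ints, C0, act, Driver.FCI)
        assert s2.converged and len(trace2.energies) <= 2
        assert s2.energy == pytest.approx(s1.energy, abs=1e-10)

    def test_warm_start_requires_nested_active_spaces(self, water_cas22):
        from quantumcas.active_space import select_active_space
        ints, scf, act = (water_cas22["ints"], water_cas22["scf"],
                          water_cas22["act"])
        s1, _ = run_casscf(ints, scf.mo_coefficients, act, Driver.FCI)
        other = select_active_space(scf, 2, [0, 6])
        with pytest.raises(ValueError):
            warm_start(s1, other)

    def test_unconverged_run_flagged_with_full_trace(self, water_cas22):
        crit = ConvergenceCriteria(energy_tol=1e-14, gradient_tol=1e-12,
                                   max_macro=2)
        state, trace = run_casscf(water_cas22["ints"],
                                  water_cas22["scf"].mo_coefficients,
                                  water_cas22["act"], Driver.FCI, crit)
        assert not state.converged
        assert len(trace.energies) == 2

    def test_driver_independence_cas22(self, water_cas22):
        sf, _ = run_casscf(water_cas22["ints"],
                           water_cas22["scf"].mo_coefficients,
                           water_cas22["act"], Driver.FCI)
        su, _ = run_casscf(water_cas22["ints"],
                           water_cas22["scf"].mo_coefficients,
                           water_cas22["act"], Driver.UCCSD_VQE)
        assert su.energy == pytest.approx(sf.energy, abs=1e-6)

    def test_warm_start_small_to_larger_cas(self, water_system):
        from quantumcas.active_space import frontier_active_space
        ints, scf = water_system["ints"], water_system["scf"]
        act2 = frontier_active_space(scf, 2, 2)
        s2, _ = run_casscf(ints, scf.mo_coefficients, act2, Driver.FCI)
        act4 = frontier_active_space(scf, 4, 4)
        cold, _ = run_casscf(ints, scf.mo_coefficients, act4, Driver.FCI)
        warm, _ = run_casscf(ints, warm_start(s2, act4), act4, Driver.FCI)
        assert warm.energy == pytest.approx(cold.energy, abs=1e-8)
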