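"""Variational quantum eigensolver: expectation values, optimizers, RDMs.

Noiseless runs evaluate exact statevector expectations and minimize with a
deterministic optimizer (SLSQP by default, zero initial UCCSD amplitudes so
the search starts at the Hartree–Fock energy).  Noisy runs evaluate
shot-sampled expectations on a density-matrix simulation of the circuit and
minimize with SPSA, whose standard gain sequences a_k = a/(k+1+A)^alpha and
c_k = c/(k+1)^gamma tolerate stochastic objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .active_space import ActiveHamiltonian
from .ansatz import (AnsatzKind, AnsatzSpec, apply_hea, apply_uccsd,
                     hea_spec, prepare_reference, uccsd_generator_matrices,
                     uccsd_spec)
from .exact import SectorSpec
from .fermion import to_spin_orbitals
from .mapping import Encoding, map_operator, rdm_component_operators
from .noise import (DensityMatrix, IDEAL, NoiseSpec, hea_density_matrix,
                    sample_pauli_expectation)
from .pauli import QubitOperator
from .rdm import RDMPair
from .statevector import Statevector

__all__ = ["OptimizerSpec", "VQEResult", "expectation", "sampled_expectation",
           "vqe_minimize", "measure_rdms", "VQEDriver", "spsa_minimize"]


@dataclass
class OptimizerSpec:
    """Classical optimizer configuration for the variational loop."""

    method: str = "slsqp"          # "slsqp", "bfgs" or "spsa"
    maxiter: int = 200
    tol: float = 1e-12
    # SPSA gain-sequence constants; with spsa_calibrate the base gain a is
    # rescaled so the first step moves each parameter by ~spsa_target_step
    spsa_a: float = 0.1
    spsa_c: float = 0.1
    spsa_alpha: float = 0.602
    spsa_gamma: float = 0.101
    spsa_A: float = 10.0
    spsa_iterations: int = 100
    spsa_calibrate: bool = True
    spsa_target_step: float = 0.15
    n_restarts: int = 1            # random restarts (HEA landscapes)


@dataclass
class VQEResult:
    energy: float
    parameters: np.ndarray
    n_evaluations: int
    optimizer_trace: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = True


def expectation(state: Statevector, op: QubitOperator) -> float:
    """Exact expectation of a Hermitian operator."""
    if not op.is_hermitian():
        raise ValueError("expectation requires a Hermitian operator")
    return float(np.real(state.expectation(op)))


def sampled_expectation(state, op: QubitOperator, shots: int,
                        noise: NoiseSpec = IDEAL, seed: int = 0) -> float:
    """Shot-sampled expectation, one measured basis per Pauli string.

    ``state`` may be a Statevector or a DensityMatrix (for circuits already
    simulated with gate noise); readout confusion from ``noise`` is applied
    to the outcome distribution before sampling.  Complex coefficients are
    allowed (for non-Hermitian RDM components); the real part is returned.
    """
    if shots < 1:
        raise ValueError("shots must be >= 1")
    rng = np.random.default_rng(seed)
    total = 0.0 + 0.0j
    for lbl, c in sorted(op.terms.items()):
        est = sample_pauli_expectation(state, lbl, shots, noise, rng)
        total += c * est
    return float(np.real(total))


def spsa_minimize(fun, x0: np.ndarray, opt: OptimizerSpec,
                  rng: np.random.Generator):
    """Simultaneous perturbation stochastic approximation (minimization)."""
    x = np.asarray(x0, float).copy()
    trace = []
    n_eval = 0
    best_x = x.copy()
    best_f = np.inf
    a = opt.spsa_a
    if opt.spsa_calibrate:
        # Spall-style gain calibration: scale a so the first update moves
        # each parameter by roughly spsa_target_step radians
        mags = []
        for _ in range(5):
            delta = rng.choice([-1.0, 1.0], size=x.shape)
            df = fun(x + opt.spsa_c * delta) - fun(x - opt.spsa_c * delta)
            n_eval += 2
            mags.append(abs(df) / (2.0 * opt.spsa_c))
        gmag = max(np.mean(mags), 1e-8)
        a = opt.spsa_target_step * (1 + opt.spsa_A) ** opt.spsa_alpha / gmag
    for k in range(opt.spsa_iterations):
        a_k = a / (k + 1 + opt.spsa_A) ** opt.spsa_alpha
        c_k = opt.spsa_c / (k + 1) ** opt.spsa_gamma
        delta = rng.choice([-1.0, 1.0], size=x.shape)
        f_plus = fun(x + c_k * delta)
        f_minus = fun(x - c_k * delta)
        n_eval += 2
        ghat = (f_plus - f_minus) / (2.0 * c_k) * (1.0 / delta)
        x = x - a_k * ghat
        f_mid = 0.5 * (f_plus + f_minus)
        trace.append((k, f_mid))
        if f_mid < best_f:
            best_f = f_mid
            best_x = x.copy()
    # return the final iterate: picking the best-seen *noisy* evaluation
    # would bias the estimate low, the more so the larger the dispersion
    if not np.all(np.isfinite(x)):
        x = best_x
    return x, trace, n_eval


def vqe_minimize(hamiltonian: QubitOperator, spec: AnsatzSpec,
                 optimizer: OptimizerSpec | None = None, seed: int = 0,
                 noise: NoiseSpec = IDEAL, shots: int | None = None,
                 initial_parameters: np.ndarray | None = None) -> VQEResult:
    """Minimize <psi(theta)|H|psi(theta)> over the ansatz parameters."""
    opt = optimizer or OptimizerSpec()
    rng = np.random.default_rng(seed)
    noisy = (shots is not None) or not noise.is_noiseless

    if spec.kind == AnsatzKind.UCCSD:
        reference = Statevector.from_bits(spec.reference_bits)
        gens = uccsd_generator_matrices(spec)
        if noisy:
            raise NotImplementedError(
                "shot/noise simulation is implemented for the HEA driver")

        def build(params):
            return apply_uccsd(reference, params, spec, gens)
        x0 = (np.zeros(spec.parameter_count)
              if initial_parameters is None else np.asarray(initial_parameters))
    elif spec.kind == AnsatzKind.HEA:
        def build(params):
            if noisy and not noise.is_noiseless:
                return hea_density_matrix(params, spec, noise)
            return apply_hea(params, spec)
        x0 = (rng.uniform(-np.pi, np.pi, spec.parameter_count)
              if initial_parameters is None else np.asarray(initial_parameters))
    else:
        raise ValueError(f"unknown ansatz kind {spec.kind!r}")

    eval_counter = [0]
    if noisy:
        shots_ = shots or 1000

        def fun(params):
            eval_counter[0] += 1
            return sampled_expectation(build(params), hamiltonian, shots_,
                                       noise,
                                       seed=int(rng.integers(2 ** 31)))
    else:
        def fun(params):
            eval_counter[0] += 1
            return expectation(build(params), hamiltonian)

    e0 = fun(x0)
    if opt.method == "spsa":
        best_x, trace, n_eval = spsa_minimize(fun, x0, opt, rng)
        energy = fun(best_x)
        return VQEResult(energy=float(energy), parameters=best_x,
                         n_evaluations=eval_counter[0], optimizer_trace=trace)

    method = {"slsqp": "SLSQP", "bfgs": "BFGS"}[opt.method]
    trace = []
    best = {"x": x0, "f": e0}
    n_restarts = opt.n_restarts if initial_parameters is None else 1
    for restart in range(max(1, n_restarts)):
        x_start = x0 if restart == 0 else rng.uniform(
            -np.pi, np.pi, spec.parameter_count)
        res = minimize(fun, x_start, method=method,
                       options={"maxiter": opt.maxiter,
                                "ftol" if method == "SLSQP" else "gtol":
                                    opt.tol})
        trace.append((restart, float(res.fun)))
        if res.fun < best["f"]:
            best = {"x": res.x, "f": float(res.fun), "converged": bool(res.success)}
    return VQEResult(energy=best["f"], parameters=np.asarray(best["x"]),
                     n_evaluations=eval_counter[0], optimizer_trace=trace,
                     converged=bool(best.get("converged", True)))


def measure_rdms(state, n_orb: int, encoding: Encoding,
                 sector: SectorSpec, shots: int | None = None,
                 noise: NoiseSpec = IDEAL, seed: int = 0,
                 operators=None) -> RDMPair:
    """1- and 2-RDM from expectation values of the mapped component operators.

    With ``shots`` (or gate noise) the entries are sampled independently, so
    the raw matrices need the downstream normalization/symmetrization
    pipeline; noiseless statevector measurement returns exact RDMs.
    """
    if operators is None:
        operators = rdm_component_operators(n_orb, encoding,
                                            sector.n_electrons, sector.sz2)
    ops1, ops2 = operators
    rng = np.random.default_rng(seed)
    sample = (shots is not None) or not noise.is_noiseless

    def value(op):
        if sample:
            return sampled_expectation(state, op, shots or 1000, noise,
                                       seed=int(rng.integers(2 ** 31)))
        return float(np.real(state.expectation(op)))

    dm1 = np.zeros((n_orb, n_orb))
    for (p, q), op in ops1.items():
        dm1[p, q] = value(op)
    dm2 = np.zeros((n_orb,) * 4)
    for (p, q, r, s), op in ops2.items():
        dm2[p, q, r, s] = value(op)
    return RDMPair(dm1=dm1, dm2=dm2, n_electrons=sector.n_electrons)


class VQEDriver:
    """Active-space solver backed by a variational ansatz.

    Presents the same surface as the exact driver: given an
    ActiveHamiltonian, produce (total energy, state, RDMs).
    """

    def __init__(self, ansatz: AnsatzKind = AnsatzKind.UCCSD,
                 encoding: Encoding = Encoding.JW,
                 optimizer: OptimizerSpec | None = None,
                 noise: NoiseSpec = IDEAL, shots: int | None = None,
                 hea_layers: int = 1, seed: int = 0):
        self.ansatz = ansatz
        self.encoding = encoding
        self.optimizer = optimizer
        self.noise = noise
        self.shots = shots
        self.hea_layers = hea_layers
        self.seed = seed
        self.last_parameters: np.ndarray | None = None

    def solve(self, h_act: ActiveHamiltonian,
              initial_parameters: np.ndarray | None = None,
              seed: int | None = None):
        sector = SectorSpec(h_act.n_active_electrons, h_act.sz2)
        f = to_spin_orbitals(h_act)
        qubit_h = map_operator(f, self.encoding, sector.n_electrons,
                               sector.sz2)
        n_orb = h_act.n_active_orbitals
        if self.ansatz == AnsatzKind.UCCSD:
            spec = uccsd_spec(n_orb, sector.n_alpha, sector.n_beta,
                              self.encoding)
            opt = self.optimizer or OptimizerSpec(method="slsqp")
        else:
            n_qubits = 2 * n_orb - (2 if self.encoding == Encoding.PARITY_REDUCED
                                    else 0)
            spec = hea_spec(n_qubits, self.hea_layers, self.encoding)
            default = "spsa" if (self.shots or not self.noise.is_noiseless) \
                else "slsqp"
            opt = self.optimizer or OptimizerSpec(method=default, n_restarts=5)
        run_seed = self.seed if seed is None else seed
        result = vqe_minimize(qubit_h, spec, opt, seed=run_seed,
                              noise=self.noise, shots=self.shots,
                              initial_parameters=initial_parameters)
        self.last_parameters = result.parameters
        # rebuild the final state for RDM measurement
        if spec.kind == AnsatzKind.UCCSD:
            state = apply_uccsd(Statevector.from_bits(spec.reference_bits),
                                result.parameters, spec)
        elif self.noise.is_noiseless:
            state = apply_hea(result.parameters, spec)
        else:
            state = hea_density_matrix(result.parameters, spec, self.noise)
        rdms = measure_rdms(state, n_orb, self.encoding, sector,
                            shots=self.shots, noise=self.noise,
                            seed=run_seed + 1)
        return result, state, rdms
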