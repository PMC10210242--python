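# quantumcas

A desk-scale simulator of the **hybrid quantum CASSCF** method: complete
active space self-consistent field calculations in which the active-space
eigenproblem is solved by a (simulated) variational quantum eigensolver
while a classical routine optimizes the molecular orbitals from measured
reduced density matrices.

It is aimed at quantum-computational-chemistry researchers who want a
small, fully inspectable reference implementation of the whole pipeline —
from Gaussian-basis integrals to noisy-shot statistics — with no external
quantum-chemistry or quantum-SDK dependencies.

## What it computes

For a molecule with Hamiltonian
`H = Σ_pq h_pq a†_p a_q + ½ Σ_pqrs (pq|rs) a†_p a†_r a_s a_q + E_nuc`,
a CAS(n, m) calculation keeps n electrons in m selected MOs exactly
correlated and treats the rest at mean field. The package provides:

* **Molecular setup** — XYZ geometries, bundled STO-3G / 6-31G / cc-pVDZ
  basis sets (NWChem-format files; user files accepted), McMurchie–Davidson
  one- and two-electron integrals over s/p/d shells, restricted HF (RHF and
  ROHF) with DIIS.
* **Active-space Hamiltonians** — the effective one-body matrix
  `h_eff = h + Σ_i [2(pq|ii) − (pi|iq)]`, active two-electron integrals,
  core energy; FCIDUMP import/export (Molpro dialect).
* **Fermion→qubit mappings** — Jordan–Wigner and parity encoding with
  two-qubit reduction, plus a small Pauli-string algebra.
* **Drivers for the active space** — exact sector-projected diagonalization
  (FCI), UCCSD-VQE on a statevector simulator (spin-adapted singles and
  doubles, exact per-generator exponentials, SLSQP), and a shallow
  hardware-efficient ansatz (Ry/Rz layers + CX chain) with SPSA, shot
  sampling, and a depolarizing + readout noise model on a density-matrix
  simulator.
* **RDM post-processing** — the measured 1-/2-RDMs are normalized
  (trace N), symmetrized, occupation-clipped to [0, 2], constrained
  (2-RDM trace N(N−1), partial trace (N−1)·dm1) and optionally
  *canonicalized* to natural orbitals.
* **Orbital optimization** — generalized-Fock orbital gradients
  `g_pq = 2(F_pq − F_qp)` over the nonredundant rotations, trust-bounded
  relaxation, macro-iterations to `ΔE < 1e-8` Ha and `‖g‖ < 1e-5`.
* **Noise benchmark harness** — repeated noisy quantum-CASSCF runs with
  per-iteration mean/std/95 % CI statistics comparing canonical versus
  noncanonical orbital processing.

## Worked example: stretched CO

Carbon monoxide stretched to a 1.54 Å bond in cc-pVDZ with a CAS(2,2)
active space (the frontier π/π* pair) is strongly correlated and small
enough to run in seconds:

```bash
quantumcas casscf --molecule co_1.54 --basis cc-pvdz --cas 2,2 --driver fci --quiet
```

prints

```
CASSCF energy: -112.587151558 Ha (converged, 23 macro-iterations)
natural occupations: 1.7466 0.2534
```

The RHF energy for this system is −112.532844 Ha, so the two-orbital
active space recovers 54 mHa of static correlation, and the natural
occupations 1.75/0.25 show the strong π→π* mixing. Replacing the exact
active-space driver with the noiseless UCCSD-VQE
(`--driver uccsd-vqe`) converges to the same energy to better than
1e-6 Ha — UCCSD is exact for two orbitals.

The same pipeline is scriptable from Python:

```python
from quantumcas.geometry import bundled_geometry
from quantumcas.integrals import compute_ao_integrals
from quantumcas.scf import run_hf
from quantumcas.active_space import frontier_active_space
from quantumcas.casscf import run_casscf, Driver

geom = bundled_geometry("co_1.54")
ints = compute_ao_integrals(geom, "cc-pvdz")
scf = run_hf(ints, geom)
act = frontier_active_space(scf, n_elec=2, n_orb=2)
state, trace = run_casscf(ints, scf.mo_coefficients, act, Driver.FCI)
print(state.energy, state.rdms.occupations())
```

A noisy experiment (1000 shots, generic depolarizing + readout noise,
HEA ansatz, SPSA, parity mapping with two-qubit reduction, 9 iterations):

```bash
quantumcas noisy-bench --molecule co_1.54 --basis cc-pvdz --cas 2,2 --repeats 20
```

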