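# Methods

This note documents the models, numerical choices and limitations behind
`quantumcas`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Electronic-structure layer

**Integrals.** One- and two-electron integrals over contracted Cartesian
Gaussians are evaluated with the McMurchie–Davidson scheme (Hermite
expansion coefficients by recursion; Hermite Coulomb integrals from the
Boys function, computed by a downward-stable series for arguments ≤ 30 and
upward recursion above). Shells up to l = 2 are supported and d shells are
used in the real-solid-harmonic representation, with the cart→spherical
coefficients written for (l,0,0)-normalized contractions. The primitive
loops are numba-compiled; a cc-pVDZ diatomic takes well under a second
after JIT warm-up. Basis data for H/C/N/O (STO-3G, 6-31G, cc-pVDZ) are
bundled as NWChem-format text transcribed from the published basis-set
tables; any NWChem-format file path is accepted for other sets
(ANO-type sets are not bundled). Units: Å on input, Bohr/Hartree
internally, conversion 0.52917721092 Å/Bohr.

**Mean field.** RHF, and ROHF (Roothaan single effective Fock with
closed–open → F^β and open–virtual → F^α couplings) for open shells, both
DIIS-accelerated from a core-Hamiltonian guess. Convergence requires an
energy change < 1e-11 Ha *and* a DIIS residual < 1e-8 (defaults). MOs are
sorted by orbital energy, ties broken by original index; HOMO/LUMO labels
follow aufbau filling.

**Active space.** Selection is by explicit MO index list (the inactive set
is then the lowest occupied MOs not selected), or by a HOMO-centred
frontier window. The effective Hamiltonian uses
`h_eff = h + Σ_i [2(pq|ii) − (pi|iq)]` and
`e_core = E_nuc + Σ_i (h_ii + F^core_ii)`; a CAS with zero active orbitals
reproduces the HF energy to 1e-10 Ha (tested).

## Qubit layer

Spin orbitals are **blocked** (α modes 0..n−1, β modes n..2n−1) — chosen
so the two parity-reduced qubits sit at the standard positions n−1 and
2n−1. Jordan–Wigner uses a†_p → (X_p − iY_p)/2 ⊗ Z-chain on lower modes;
the parity encoding stores cumulative parities and removes the α-parity
and total-parity qubits for operators conserving particle number and Sz,
substituting their sector eigenvalues (−1)^{n_α}, (−1)^{N}. Both encodings
are cross-checked against a dense occupation-number-ladder oracle and
against each other (sector spectra to 1e-10). Coefficient pruning
tolerance is 1e-12.

## Variational drivers

**UCCSD** applies one first-order Trotter step of spin-adapted singlet
singles/doubles generators (Sz-conserving spin-orbital excitations for
open shells) to the aufbau reference, each generator exponentiated
exactly (sparse Krylov `expm_multiply`). Generator order is lexicographic,
occupied index major. Amplitudes start at zero, so the optimization
starts from the HF energy; the default optimizer is SLSQP with ftol
1e-12. For a 2-orbital active space UCCSD is exact; the suite asserts
agreement with the exact driver to 1e-9 Ha.

**HEA** is `L × [Ry layer, Rz layer, linear CX chain] + closing Ry+Rz`
on |0…0⟩, default L = 1. This layout is this package's choice of a
shallow hardware-style circuit; any layout able to reach the 2-qubit
ground manifold would do. Noiseless HEA optimization uses SLSQP with five
random restarts (the landscape has local minima); noisy optimization uses
SPSA.

**SPSA** uses the standard gain sequences a_k = a/(k+1+A)^0.602,
c_k = c/(k+1)^0.101 with c = 0.1, A = 10 and 100 iterations by default.
The base gain `a` is calibrated per run (Spall's rule) so the first
update moves parameters by ≈ 0.15 rad; a fixed a = 0.1 left the 2-qubit
problem visibly under-converged. SPSA returns the final iterate: returning
the best-seen noisy evaluation would bias energies low, the more so the
larger the run-to-run dispersion, which would contaminate the
canonical-vs-noncanonical comparison.

**Noise model.** A generic parameterized model stands in for any
device-calibrated one: depolarizing channels after every gate (separate
1q/2q probabilities; `p` is the probability of replacing the subsystem by
the maximally mixed state) on a density-matrix simulation of the circuit,
plus symmetric per-qubit readout confusion applied to the outcome
distribution before multinomial shot sampling. Defaults: 1q 1e-3,
2q 1e-2, readout 2e-2, 1000 shots — chosen once to give energy errors of
a few tens of mHa on the 2-qubit benchmark, the order seen on entry-level
superconducting devices. When sampling directly from a statevector (no
circuit), the 1q depolarizing parameter acts as a pre-measurement
channel, i.e. a symmetric outcome flip with probability p/2. Every Pauli
string is measured in its own diagonalizing basis; no term grouping.

## RDM measurement and processing

1-RDM entries are expectations of the mapped spin-summed E_pq
(every (p,q) measured independently, so noisy estimates are genuinely
asymmetric); 2-RDM entries are expectations of
e_pqrs = E_pq E_rs − δ_qr E_ps, the chemist-ordered spin-summed
convention with full trace N(N−1) and partial trace (N−1)·dm1.

The processing pipeline, in order: (1) rescale dm1 to trace N;
(2) symmetrize; (3) project natural occupations onto
{0 ≤ n ≤ 2, Σn = N} (an exact capped-simplex projection — a plain
clip-and-rescale is not idempotent when an occupation saturates);
(4) constrain dm2: symmetrize over the (pq)↔(rs) and hermitian index
exchanges, rescale the full trace to N(N−1), and remove the
partial-trace defect with a symmetric rank-reduced correction so a second
pass is a no-op; (5) optionally diagonalize dm1 (descending occupations,
eigenvector signs fixed by the largest-magnitude component) and co-rotate
dm2 and the active MO columns. The whole pipeline is idempotent to 1e-12
and exact noiseless RDMs pass through unchanged to 1e-10 (both tested).
Whether to rescale or project the 2-RDM constraints is not uniquely
determined; this package projects after rescaling, in that order.

## Orbital optimization

The orbital gradient is the antisymmetrized generalized Fock matrix,
g_pq = 2(F_pq − F_qp), restricted to inactive–active, inactive–virtual
and active–virtual rotations (active–active rotations are redundant and
fixed by the canonicalization convention; inactive orbitals are optimized,
not frozen). F uses the standard spin-free construction: inactive rows
2(F^i+F^a), active rows D F^i + Q with Q_up = Σ d_uvwx (pv|wx). The
gradient is verified against central finite differences of the frozen-RDM
energy to 1e-6.

Two relaxation schemes share this gradient:

* **Trust-bounded L-BFGS (default).** Minimizes the frozen-RDM energy
  over κ within |κ| ≤ 0.2 rad per element, rebasing each macro-iteration.
  The gradient supplied at rotated points is the generalized-Fock gradient
  there (exact at κ = 0, O(|κ|²) inside the box). This variant is
  invariant under active-basis rotations and converges the tight runs
  (ΔE < 1e-8 Ha, ‖g‖ < 1e-5) in ~20 macro-iterations for the CO benchmark.
* **Single diagonal-Hessian step (noisy benchmark).** One first-order
  update κ = −g/H per macro-iteration with the super-CI-style estimate
  H_pq ≈ 2(f_q − f_p)(n_p − n_q) (f = diag of F^i+F^a, n = *diagonal*
  occupations), floored at 0.05 and trust-clipped. The estimate ignores
  1-RDM off-diagonals, so its quality depends on the active-orbital basis
  — the regime the canonical-vs-noncanonical study probes. It is not used
  for tight convergence: near orbital degeneracies (the π* pair of
  stretched CO) the floored Hessian can cycle.

Convergence requires both ΔE and ‖g‖ below tolerance; noisy runs use the
loose settings (ΔE < 1e-5, 9-iteration cap), with ΔE taken from the last
two macro-iteration energies without smoothing.

## Noisy benchmark harness

Each experiment fixes molecule, CAS, HEA + SPSA, parity-reduced mapping,
noise and the canonical flag, runs the full loop `n_repeats` times with
seeds `base + i`, pads early-converged runs by carrying the last energy
forward, and reports per-iteration mean, sample std (ddof = 1) and a
normal-approximation 95 % half-width 1.96·std/√n. Both "averaged over
iterations" and raw per-iteration dispersions are reported, since the
aggregation convention is ambiguous. The VQE is re-initialized each
macro-iteration (no parameter warm start): warm-started parameters would
be invalidated by the natural-orbital rotation in the canonical arm only,
confounding the comparison.

## What the synthetic fixtures do and do not capture

The fixture generators (dense random integrals with 8-fold symmetry, a
1D Hubbard-type chain at U/t = 4, a stretched minimal-basis H₂ from the
package's own integrals) exercise every operator-algebra and driver code
path with exactly known ground energies. They do not emulate basis-set
incompleteness, core–valence separation in large molecules, or
device-calibrated noise, so passing tests demonstrate internal
consistency of the pipeline, not quantitative agreement with hardware
experiments. The bundled water geometry is a synthetic fixture at the
standard experimental structure, used for structural tests only.

## Known limitations

* Integrals stop at d shells; no f-function basis sets.
* Exact diagonalization and the statevector scale exponentially; intended
  for ≤ 6 active orbitals / ≤ 12 qubits.
* No measurement grouping, no error mitigation, no device topology.
* The noise study's quantitative outcomes depend on the generic noise
  parameters; only directional/statistical behavior is meaningful.
* Second-order (coupled orbital-CI) convergence acceleration, excited
  states and state averaging are out of scope.
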