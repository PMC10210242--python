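"""Parameterized ansätze: UCCSD (chemistry-inspired) and hardware-efficient.

UCCSD applies a single first-order Trotter step of the anti-Hermitian
cluster operator to an aufbau reference determinant; each generator is
exponentiated exactly (sparse Krylov).  Closed-shell references use
spin-adapted singlet generators; open-shell references fall back to
Sz-conserving spin-orbital excitations.  Generator order is fixed and
lexicographic (singles first, occupied index major) for reproducibility.

The hardware-efficient ansatz (HEA) is a shallow circuit of single-qubit
Ry/Rz rotation layers with a linear CX entangler chain, acting on |0...0>.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse.linalg as spla

from .fermion import FermionOperator
from .mapping import Encoding, encode_occupations, map_operator
from .statevector import Statevector

__all__ = ["AnsatzKind", "AnsatzSpec", "uccsd_spec", "hea_spec",
           "prepare_reference", "apply_uccsd", "apply_hea", "hea_circuit"]


class AnsatzKind(str, Enum):
    UCCSD = "uccsd"
    HEA = "hea"


@dataclass
class AnsatzSpec:
    """Structure of a parameterized ansatz (no parameter values)."""

    kind: AnsatzKind
    n_qubits: int
    parameter_count: int
    n_orbitals: int = 0
    n_alpha: int = 0
    n_beta: int = 0
    encoding: Encoding = Encoding.JW
    excitations: list = field(default_factory=list)   # UCCSD generator info
    layers: int = 1                                   # HEA depth
    reference_bits: np.ndarray | None = None


def reference_occupations(n_orb: int, n_alpha: int, n_beta: int) -> np.ndarray:
    """Blocked spin-orbital occupation vector of the aufbau determinant."""
    occ = np.zeros(2 * n_orb, dtype=int)
    occ[:n_alpha] = 1
    occ[n_orb:n_orb + n_beta] = 1
    return occ


def prepare_reference(n_orb: int, n_alpha: int, n_beta: int,
                      encoding: Encoding = Encoding.JW) -> Statevector:
    """Computational-basis state encoding the aufbau (HF) determinant."""
    occ = reference_occupations(n_orb, n_alpha, n_beta)
    return Statevector.from_bits(encode_occupations(occ, encoding))


def _singlet_generators(n_orb: int, n_occ: int):
    """Spin-adapted closed-shell singles and doubles generators."""
    occ = range(n_occ)
    virt = range(n_occ, n_orb)
    singles = [("s", i, a) for i in occ for a in virt]
    pairs = [(i, a) for i in occ for a in virt]
    doubles = []
    for k, (i, a) in enumerate(pairs):
        for j, b in pairs[k:]:
            doubles.append(("d", i, a, j, b))
    return singles + doubles


def _spin_orbital_generators(n_orb: int, n_alpha: int, n_beta: int):
    """Sz-conserving spin-orbital singles/doubles for open shells."""
    occ = list(range(n_alpha)) + [n_orb + b for b in range(n_beta)]
    virt = [p for p in range(2 * n_orb) if p not in occ]
    spin = lambda so: 0 if so < n_orb else 1
    singles = [("so_s", o, v) for o in occ for v in virt
               if spin(o) == spin(v)]
    doubles = []
    for ko, o1 in enumerate(occ):
        for o2 in occ[ko + 1:]:
            for kv, v1 in enumerate(virt):
                for v2 in virt[kv + 1:]:
                    if spin(o1) + spin(o2) == spin(v1) + spin(v2):
                        doubles.append(("so_d", o1, o2, v1, v2))
    return singles + doubles


def uccsd_spec(n_orb: int, n_alpha: int, n_beta: int,
               encoding: Encoding = Encoding.JW) -> AnsatzSpec:
    if n_alpha == n_beta:
        excitations = _singlet_generators(n_orb, n_alpha)
    else:
        excitations = _spin_orbital_generators(n_orb, n_alpha, n_beta)
    n_qubits = 2 * n_orb - (2 if encoding == Encoding.PARITY_REDUCED else 0)
    ref = encode_occupations(reference_occupations(n_orb, n_alpha, n_beta),
                             encoding)
    return AnsatzSpec(kind=AnsatzKind.UCCSD, n_qubits=n_qubits,
                      parameter_count=len(excitations), n_orbitals=n_orb,
                      n_alpha=n_alpha, n_beta=n_beta, encoding=encoding,
                      excitations=excitations, reference_bits=ref)


def _excitation_generator(exc, n_orb: int) -> FermionOperator:
    """Anti-Hermitian generator T - T^dag for one excitation label."""
    nm = 2 * n_orb
    T = FermionOperator(nm)
    kind = exc[0]
    if kind == "s":
        _, i, a = exc
        T.add_term(((a, True), (i, False)), 1.0)
        T.add_term(((a + n_orb, True), (i + n_orb, False)), 1.0)
    elif kind == "d":
        _, i, a, j, b = exc
        # E_ai E_bj expanded over spins
        for s1 in (0, n_orb):
            for s2 in (0, n_orb):
                T.add_term(((a + s1, True), (i + s1, False),
                            (b + s2, True), (j + s2, False)), 1.0)
    elif kind == "so_s":
        _, o, v = exc
        T.add_term(((v, True), (o, False)), 1.0)
    elif kind == "so_d":
        _, o1, o2, v1, v2 = exc
        T.add_term(((v2, True), (v1, True), (o2, False), (o1, False)), 1.0)
    else:
        raise ValueError(f"unknown excitation {exc!r}")
    return T + (-1.0) * T.dagger()


def uccsd_generator_matrices(spec: AnsatzSpec):
    """Sparse anti-Hermitian qubit matrices of the UCCSD generators."""
    n_elec = spec.n_alpha + spec.n_beta
    sz2 = spec.n_alpha - spec.n_beta
    mats = []
    for exc in spec.excitations:
        G = _excitation_generator(exc, spec.n_orbitals)
        q = map_operator(G, spec.encoding, n_elec, sz2)
        mats.append(q.to_sparse())
    return mats


def apply_uccsd(reference: Statevector, params: np.ndarray, spec: AnsatzSpec,
                generator_matrices=None) -> Statevector:
    """|psi> = prod_k exp(theta_k G_k) |ref>, exact per-generator exponential."""
    params = np.asarray(params, float)
    if params.shape[0] != spec.parameter_count:
        raise ValueError(f"expected {spec.parameter_count} parameters")
    if generator_matrices is None:
        generator_matrices = uccsd_generator_matrices(spec)
    amp = reference.amplitudes.copy()
    for theta, G in zip(params, generator_matrices):
        if theta != 0.0:
            amp = spla.expm_multiply(theta * G, amp)
    return Statevector(amp)


# ---------------------------------------------------------------------------
# hardware-efficient ansatz
# ---------------------------------------------------------------------------

def hea_spec(n_qubits: int, layers: int = 1,
             encoding: Encoding = Encoding.PARITY_REDUCED) -> AnsatzSpec:
    return AnsatzSpec(kind=AnsatzKind.HEA, n_qubits=n_qubits,
                      parameter_count=2 * n_qubits * (layers + 1),
                      layers=layers, encoding=encoding)


def hea_circuit(params: np.ndarray, spec: AnsatzSpec):
    """Gate list [(name, qubit(s), angle), ...] for the HEA circuit.

    Layout: L x [Ry layer, Rz layer, linear CX chain] + closing Ry+Rz layer.
    """
    params = np.asarray(params, float)
    if params.shape[0] != spec.parameter_count:
        raise ValueError(f"expected {spec.parameter_count} parameters")
    n = spec.n_qubits
    gates = []
    k = 0
    for _ in range(spec.layers):
        for q in range(n):
            gates.append(("ry", q, params[k])); k += 1
        for q in range(n):
            gates.append(("rz", q, params[k])); k += 1
        for q in range(n - 1):
            gates.append(("cx", (q, q + 1), None))
    for q in range(n):
        gates.append(("ry", q, params[k])); k += 1
    for q in range(n):
        gates.append(("rz", q, params[k])); k += 1
    return gates


def _ry(theta):
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _rz(theta):
    return np.array([[np.exp(-0.5j * theta), 0], [0, np.exp(0.5j * theta)]],
                    dtype=complex)


GATE_MATS = {"ry": _ry, "rz": _rz}


def apply_1q_gate(amp: np.ndarray, U: np.ndarray, q: int, n: int) -> np.ndarray:
    full = amp.reshape([2] * n)
    # qubit 0 is the least-significant bit -> last axis in C order
    axis = n - 1 - q
    full = np.moveaxis(full, axis, 0)
    full = np.tensordot(U, full, axes=([1], [0]))
    full = np.moveaxis(full, 0, axis)
    return full.reshape(-1)


def apply_cx(amp: np.ndarray, control: int, target: int, n: int) -> np.ndarray:
    idx = np.arange(amp.shape[0])
    ctrl_set = (idx >> control) & 1 == 1
    out = amp.copy()
    out[idx[ctrl_set]] = amp[idx[ctrl_set] ^ (1 << target)]
    return out


def apply_hea(params: np.ndarray, spec: AnsatzSpec) -> Statevector:
    """Noiseless statevector of the HEA circuit on |0...0>."""
    n = spec.n_qubits
    amp = np.zeros(2 ** n, dtype=complex)
    amp[0] = 1.0
    for name, q, angle in hea_circuit(params, spec):
        if name == "cx":
            amp = apply_cx(amp, q[0], q[1], n)
        else:
            amp = apply_1q_gate(amp, GATE_MATS[name](angle), q, n)
    return Statevector(amp)
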