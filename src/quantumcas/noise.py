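"""Parameterized noise model and a small density-matrix simulator.

The model is a generic stand-in for a calibrated superconducting-device
noise model: depolarizing channels after every gate (separate 1- and
2-qubit strengths) plus per-qubit readout confusion at measurement.
Depolarizing probability ``p`` means the affected subsystem is replaced by
the maximally mixed state with probability ``p``, so ``p = 1`` wipes out
any traceless observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ansatz import GATE_MATS, AnsatzSpec, hea_circuit

__all__ = ["NoiseSpec", "DensityMatrix", "hea_density_matrix",
           "measurement_probabilities", "sample_pauli_expectation"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise parameters for sampled/noisy simulation.

    ``readout_flip`` is the probability of reading each qubit's outcome
    wrong (symmetric confusion; rows of the 2x2 confusion matrix are
    [1-f, f] / [f, 1-f]).
    """

    depolarizing_1q: float = 0.0
    depolarizing_2q: float = 0.0
    readout_flip: float = 0.0
    shots: int | None = None

    def __post_init__(self):
        for name in ("depolarizing_1q", "depolarizing_2q", "readout_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def is_noiseless(self) -> bool:
        return (self.depolarizing_1q == 0.0 and self.depolarizing_2q == 0.0
                and self.readout_flip == 0.0)


IDEAL = NoiseSpec()

# defaults chosen to give energy errors of the order seen on entry-level
# superconducting hardware
DEFAULT_NOISE = NoiseSpec(depolarizing_1q=1e-3, depolarizing_2q=1e-2,
                          readout_flip=2e-2, shots=1000)


class DensityMatrix:
    """Dense density operator on a few qubits (little-endian, like Statevector)."""

    def __init__(self, rho: np.ndarray, n_qubits: int):
        self.rho = rho
        self.n_qubits = n_qubits

    @classmethod
    def zero_state(cls, n_qubits: int) -> "DensityMatrix":
        dim = 2 ** n_qubits
        rho = np.zeros((dim, dim), dtype=complex)
        rho[0, 0] = 1.0
        return cls(rho, n_qubits)

    def _full_1q(self, U: np.ndarray, q: int) -> np.ndarray:
        mats = [U if j == q else np.eye(2, dtype=complex)
                for j in range(self.n_qubits)]
        full = mats[-1]
        for m in mats[-2::-1]:
            full = np.kron(full, m)
        return full

    def apply_unitary(self, U_full: np.ndarray) -> None:
        self.rho = U_full @ self.rho @ U_full.conj().T

    def apply_1q(self, U: np.ndarray, q: int) -> None:
        self.apply_unitary(self._full_1q(U, q))

    def apply_cx(self, control: int, target: int) -> None:
        dim = 2 ** self.n_qubits
        perm = np.arange(dim)
        ctrl = (perm >> control) & 1 == 1
        perm[ctrl] = perm[ctrl] ^ (1 << target)
        self.rho = self.rho[np.ix_(perm, perm)]

    def depolarize(self, qubits: tuple[int, ...], p: float) -> None:
        if p == 0.0:
            return
        self.rho = (1.0 - p) * self.rho \
            + p * _mix_qubits(self.rho, self.n_qubits, qubits)

    def probabilities(self) -> np.ndarray:
        return np.real(np.diag(self.rho)).clip(min=0.0)

    def expectation(self, op_matrix: np.ndarray) -> float:
        return float(np.real(np.trace(op_matrix @ self.rho)))


def _mix_qubits(rho: np.ndarray, n: int, qubits: tuple[int, ...]) -> np.ndarray:
    """Tr_qubits(rho) ⊗ I/2^k re-embedded on the original qubit positions.

    In the reshaped (2,)*2n tensor, the bra axis of qubit q is n-1-q and
    its ket axis 2n-1-q; each qubit is traced out and replaced by I/2.
    """
    t = rho.reshape([2] * (2 * n))
    eye = np.eye(2) / 2.0
    for q in qubits:
        ax_bra = n - 1 - q
        ax_ket = 2 * n - 1 - q
        t = np.trace(t, axis1=ax_bra, axis2=ax_ket)
        t = np.tensordot(t, eye, axes=0)
        t = np.moveaxis(t, (t.ndim - 2, t.ndim - 1), (ax_bra, ax_ket))
    return t.reshape(rho.shape)


def hea_density_matrix(params: np.ndarray, spec: AnsatzSpec,
                       noise: NoiseSpec) -> DensityMatrix:
    """Run the HEA circuit with per-gate depolarizing noise."""
    dm = DensityMatrix.zero_state(spec.n_qubits)
    for name, q, angle in hea_circuit(params, spec):
        if name == "cx":
            dm.apply_cx(q[0], q[1])
            dm.depolarize(q, noise.depolarizing_2q)
        else:
            dm.apply_1q(GATE_MATS[name](angle), q)
            dm.depolarize((q,), noise.depolarizing_1q)
    return dm


# ---------------------------------------------------------------------------
# Pauli measurement with shots and readout error
# ---------------------------------------------------------------------------

_H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)
_SDG_H = np.array([[1, -1j], [1, 1j]], dtype=complex) / np.sqrt(2)


def _basis_rotation(ch: str) -> np.ndarray | None:
    if ch == "X":
        return _H
    if ch == "Y":
        return _SDG_H
    return None


def measurement_probabilities(state_or_dm, label: str,
                              noise: NoiseSpec) -> np.ndarray:
    """Outcome probabilities for measuring one Pauli string.

    Applies the diagonalizing single-qubit rotations, then the classical
    measurement channels on the measured qubits: for bare statevectors
    (no circuit to attach gate noise to) ``depolarizing_1q`` acts as a
    pre-measurement depolarizing channel, i.e. a symmetric outcome flip
    with probability p/2; readout confusion flips with probability
    ``readout_flip``.  Accepts a Statevector or a DensityMatrix.
    """
    from .statevector import Statevector

    n = state_or_dm.n_qubits
    support = [j for j, ch in enumerate(label) if ch != "I"]
    is_statevector = isinstance(state_or_dm, Statevector)
    if is_statevector:
        from .ansatz import apply_1q_gate
        amp = state_or_dm.amplitudes
        for j in support:
            U = _basis_rotation(label[j])
            if U is not None:
                amp = apply_1q_gate(amp, U, j, n)
        probs = np.abs(amp) ** 2
    else:
        dm = DensityMatrix(state_or_dm.rho.copy(), n)
        for j in support:
            U = _basis_rotation(label[j])
            if U is not None:
                dm.apply_1q(U, j)
        probs = dm.probabilities()
    flip = noise.readout_flip
    if is_statevector:
        # depolarizing restricted to the measurement diagonal
        d = 0.5 * noise.depolarizing_1q
        flip = flip * (1 - d) + d * (1 - flip)
    if flip > 0.0:
        conf = np.array([[1 - flip, flip], [flip, 1 - flip]])
        t = probs.reshape([2] * n)
        for j in support:
            ax = n - 1 - j
            t = np.moveaxis(np.tensordot(conf, np.moveaxis(t, ax, 0),
                                         axes=([1], [0])), 0, ax)
        probs = t.reshape(-1)
    total = probs.sum()
    return probs / total if total > 0 else probs


def sample_pauli_expectation(state_or_dm, label: str, shots: int,
                             noise: NoiseSpec, rng: np.random.Generator) -> float:
    """Shot-sampled estimate of <P> for one Pauli string."""
    support_mask = sum(1 << j for j, ch in enumerate(label) if ch != "I")
    if support_mask == 0:
        return 1.0
    probs = measurement_probabilities(state_or_dm, label, noise)
    counts = rng.multinomial(shots, probs)
    idx = np.arange(probs.shape[0], dtype=np.uint64)
    parity = (np.bitwise_count(idx & np.uint64(support_mask))
              & np.uint64(1)).astype(float)
    values = 1.0 - 2.0 * parity
    return float((counts * values).sum() / shots)
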