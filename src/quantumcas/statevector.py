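"""Dense statevector representation for small qubit registers."""

from __future__ import annotations

import numpy as np

from .pauli import QubitOperator

__all__ = ["Statevector"]


class Statevector:
    """Complex amplitudes over the 2^n computational basis.

    Qubit j is bit j of the basis index (little-endian).
    """

    __slots__ = ("amplitudes", "n_qubits")

    def __init__(self, amplitudes: np.ndarray, normalize: bool = False):
        amplitudes = np.asarray(amplitudes, dtype=complex)
        n = int(np.log2(amplitudes.shape[0]))
        if 2 ** n != amplitudes.shape[0]:
            raise ValueError("amplitude length must be a power of 2")
        if normalize:
            amplitudes = amplitudes / np.linalg.norm(amplitudes)
        self.amplitudes = amplitudes
        self.n_qubits = n

    @classmethod
    def zero_state(cls, n_qubits: int) -> "Statevector":
        amp = np.zeros(2 ** n_qubits, dtype=complex)
        amp[0] = 1.0
        return cls(amp)

    @classmethod
    def from_bits(cls, bits) -> "Statevector":
        """Basis state with qubit j set to bits[j]."""
        bits = np.asarray(bits, dtype=int)
        idx = int(sum(int(b) << j for j, b in enumerate(bits)))
        amp = np.zeros(2 ** len(bits), dtype=complex)
        amp[idx] = 1.0
        return cls(amp)

    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def expectation(self, op: QubitOperator) -> complex:
        if op.n_qubits != self.n_qubits:
            raise ValueError("operator/state qubit mismatch")
        return op.expectation(self.amplitudes)

    def overlap(self, other: "Statevector") -> complex:
        return complex(np.vdot(self.amplitudes, other.amplitudes))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2

    def copy(self) -> "Statevector":
        return Statevector(self.amplitudes.copy())
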