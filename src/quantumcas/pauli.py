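"""Pauli-string algebra for qubit operators.

A Pauli string is a length-n label over {I, X, Y, Z}; character j acts on
qubit j, and qubit j is bit j (little-endian) of a computational basis index.
A :class:`QubitOperator` is a linear combination of Pauli strings and
supports sums, products (with correct phases), pruning and dense/sparse
matrix realizations.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["QubitOperator", "identity_label"]

# single-qubit multiplication table: (a, b) -> (phase, product)
_MUL = {
    ("I", "I"): (1, "I"), ("I", "X"): (1, "X"), ("I", "Y"): (1, "Y"), ("I", "Z"): (1, "Z"),
    ("X", "I"): (1, "X"), ("Y", "I"): (1, "Y"), ("Z", "I"): (1, "Z"),
    ("X", "X"): (1, "I"), ("Y", "Y"): (1, "I"), ("Z", "Z"): (1, "I"),
    ("X", "Y"): (1j, "Z"), ("Y", "X"): (-1j, "Z"),
    ("Y", "Z"): (1j, "X"), ("Z", "Y"): (-1j, "X"),
    ("Z", "X"): (1j, "Y"), ("X", "Z"): (-1j, "Y"),
}

_PAULI_MATS = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


def identity_label(n_qubits: int) -> str:
    return "I" * n_qubits


def _mul_labels(a: str, b: str) -> tuple[complex, str]:
    phase = 1 + 0j
    out = []
    for ca, cb in zip(a, b):
        ph, c = _MUL[(ca, cb)]
        phase *= ph
        out.append(c)
    return phase, "".join(out)


class QubitOperator:
    """Weighted sum of Pauli strings on a fixed number of qubits."""

    __slots__ = ("n_qubits", "terms")

    def __init__(self, n_qubits: int,
                 terms: dict[str, complex] | None = None):
        self.n_qubits = n_qubits
        self.terms: dict[str, complex] = dict(terms or {})

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_label(cls, label: str, coeff: complex = 1.0) -> "QubitOperator":
        return cls(len(label), {label: coeff})

    @classmethod
    def identity(cls, n_qubits: int, coeff: complex = 1.0) -> "QubitOperator":
        return cls(n_qubits, {identity_label(n_qubits): coeff})

    @classmethod
    def zero(cls, n_qubits: int) -> "QubitOperator":
        return cls(n_qubits, {})

    def copy(self) -> "QubitOperator":
        return QubitOperator(self.n_qubits, dict(self.terms))

    # -- algebra ----------------------------------------------------------
    def __add__(self, other: "QubitOperator") -> "QubitOperator":
        self._check(other)
        out = dict(self.terms)
        for lbl, c in other.terms.items():
            out[lbl] = out.get(lbl, 0.0) + c
        return QubitOperator(self.n_qubits, out)

    def __sub__(self, other: "QubitOperator") -> "QubitOperator":
        return self + (other * -1.0)

    def __mul__(self, other):
        if isinstance(other, QubitOperator):
            self._check(other)
            out: dict[str, complex] = {}
            for la, ca in self.terms.items():
                for lb, cb in other.terms.items():
                    ph, lbl = _mul_labels(la, lb)
                    out[lbl] = out.get(lbl, 0.0) + ph * ca * cb
            return QubitOperator(self.n_qubits, out)
        return QubitOperator(self.n_qubits,
                             {l: c * other for l, c in self.terms.items()})

    __rmul__ = __mul__

    def _check(self, other: "QubitOperator") -> None:
        if self.n_qubits != other.n_qubits:
            raise ValueError("qubit-count mismatch")

    def dagger(self) -> "QubitOperator":
        return QubitOperator(self.n_qubits,
                             {l: np.conjugate(c) for l, c in self.terms.items()})

    # -- housekeeping -----------------------------------------------------
    def simplify(self, tol: float = 1e-12) -> "QubitOperator":
        """Drop terms with |coefficient| <= tol; make real coefficients real."""
        if tol < 0:
            raise ValueError("tol must be >= 0")
        out = {}
        for lbl, c in self.terms.items():
            c = complex(c)
            if abs(c) <= tol:
                continue
            if abs(c.imag) <= tol:
                c = c.real
            out[lbl] = c
        return QubitOperator(self.n_qubits, out)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return all(abs(np.imag(c)) <= tol for c in self.terms.values())

    def coefficient(self, label: str) -> complex:
        return self.terms.get(label, 0.0)

    # -- realization ------------------------------------------------------
    def to_sparse(self) -> sp.csr_matrix:
        dim = 2 ** self.n_qubits
        out = sp.csr_matrix((dim, dim), dtype=complex)
        for lbl, c in self.terms.items():
            mat = sp.identity(1, dtype=complex, format="csr")
            # qubit 0 is the least-significant bit -> rightmost kron factor
            for ch in reversed(lbl):
                mat = sp.kron(mat, sp.csr_matrix(_PAULI_MATS[ch]), format="csr")
            out = out + c * mat
        return out

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    def apply(self, amplitudes: np.ndarray) -> np.ndarray:
        """Apply the operator to a 2^n amplitude vector (vectorized)."""
        dim = amplitudes.shape[0]
        idx = np.arange(dim, dtype=np.uint64)
        out = np.zeros(dim, dtype=complex)
        for lbl, c in self.terms.items():
            xmask = np.uint64(0)
            phasemask = np.uint64(0)   # Z and Y positions pick up (-1)^bit
            ny = 0
            for j, ch in enumerate(lbl):
                if ch in ("X", "Y"):
                    xmask |= np.uint64(1 << j)
                if ch in ("Z", "Y"):
                    phasemask |= np.uint64(1 << j)
                if ch == "Y":
                    ny += 1
            signs = 1.0 - 2.0 * (np.bitwise_count(idx & phasemask) & np.uint64(1)).astype(float)
            phase = c * (1j) ** ny
            out[idx ^ xmask] += phase * signs * amplitudes
        return out

    def expectation(self, amplitudes: np.ndarray) -> complex:
        return complex(np.vdot(amplitudes, self.apply(amplitudes)))

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        """One term per line: ``coefficient<TAB>label`` (sorted labels)."""
        lines = []
        for lbl in sorted(self.terms):
            c = complex(self.terms[lbl])
            coeff = repr(c.real) if c.imag == 0 else repr(c)
            lines.append(f"{coeff}\t{lbl}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_text(cls, text: str) -> "QubitOperator":
        terms = {}
        n = None
        for line in text.splitlines():
            if not line.strip():
                continue
            coeff_s, lbl = line.split("\t")
            if n is None:
                n = len(lbl)
            elif len(lbl) != n:
                raise ValueError("inconsistent label lengths")
            terms[lbl] = complex(coeff_s)
        if n is None:
            raise ValueError("empty operator text")
        return cls(n, terms)

    def __repr__(self) -> str:
        return f"QubitOperator(n_qubits={self.n_qubits}, n_terms={self.n_terms})"
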