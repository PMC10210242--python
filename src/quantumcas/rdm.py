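"""Reduced-density-matrix containers and the noise-mitigation pipeline.

Conventions (spin-summed, chemist ordering):

* ``dm1[p, q]`` is <E_pq>; trace equals the active electron count N.
* ``dm2[p, q, r, s]`` is <E_pq E_rs - delta_qr E_ps>; its full trace
  (sum over d_ppqq) equals N(N-1) and its partial trace over the last two
  indices gives (N-1) dm1.

The processing pipeline applied to noisy measured RDMs before orbital
optimization is: normalization -> symmetrization -> (optional)
canonicalization to natural orbitals; the 2-RDM is constrained to match.
Occupations outside [0, 2] (possible under sampling noise) are clipped and
the trace re-imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RDMPair", "NaturalOrbitalTransform", "normalize_dm1",
           "symmetrize_dm1", "canonicalize", "constrain_dm2",
           "process_rdms", "RDMError"]


class RDMError(ValueError):
    """Degenerate measured RDMs (e.g. non-positive trace)."""


@dataclass
class RDMPair:
    """Spin-summed 1- and 2-RDM with processing flags."""

    dm1: np.ndarray
    dm2: np.ndarray
    n_electrons: int
    normalized: bool = False
    symmetrized: bool = False
    canonicalized: bool = False

    @property
    def n_orbitals(self) -> int:
        return self.dm1.shape[0]

    def copy(self) -> "RDMPair":
        return replace(self, dm1=self.dm1.copy(), dm2=self.dm2.copy())

    def occupations(self) -> np.ndarray:
        """Natural occupations (descending eigenvalues of the 1-RDM)."""
        sym = 0.5 * (self.dm1 + self.dm1.T)
        return np.linalg.eigvalsh(sym)[::-1]


@dataclass
class NaturalOrbitalTransform:
    """Orthogonal rotation diagonalizing the 1-RDM, occupations descending."""

    occupations: np.ndarray
    rotation: np.ndarray          # columns are natural orbitals


def normalize_dm1(r: RDMPair) -> RDMPair:
    """Rescale dm1 so its trace is exactly the electron count."""
    tr = float(np.trace(r.dm1))
    if tr <= 0.0:
        raise RDMError(f"1-RDM trace {tr:.3e} is not positive")
    out = r.copy()
    out.dm1 *= r.n_electrons / tr
    out.normalized = True
    return out


def symmetrize_dm1(r: RDMPair) -> RDMPair:
    """Replace dm1 by its symmetric part (Frobenius projection)."""
    out = r.copy()
    out.dm1 = 0.5 * (out.dm1 + out.dm1.T)
    out.symmetrized = True
    return out


def _deterministic_eigh(sym: np.ndarray):
    """Eigendecomposition with descending eigenvalues and fixed vector signs."""
    w, U = np.linalg.eigh(sym)
    w = w[::-1]
    U = U[:, ::-1]
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return w, U


def canonicalize(r: RDMPair) -> tuple[RDMPair, NaturalOrbitalTransform]:
    """Diagonalize the 1-RDM; rotate both RDMs to the natural-orbital basis.

    The returned rotation is meant to be applied to the active MO
    coefficients as well, so that orbitals and densities stay consistent.
    """
    if not np.allclose(r.dm1, r.dm1.T, atol=1e-8):
        raise RDMError("canonicalize requires a symmetric 1-RDM")
    occ, U = _deterministic_eigh(0.5 * (r.dm1 + r.dm1.T))
    out = r.copy()
    out.dm1 = np.diag(occ)
    out.dm2 = np.einsum("pqrs,pi,qj,rk,sl->ijkl", r.dm2, U, U, U, U,
                        optimize=True)
    out.canonicalized = True
    return out, NaturalOrbitalTransform(occupations=occ, rotation=U)


def clip_occupations(r: RDMPair) -> RDMPair:
    """Project natural occupations onto {0 <= n_p <= 2, sum n_p = N}.

    Euclidean projection onto the capped simplex (shift-and-clip with the
    shift found by bisection), so occupations land exactly in-bounds with
    the exact trace, and re-projection is a no-op.
    """
    sym = 0.5 * (r.dm1 + r.dm1.T)
    w, U = _deterministic_eigh(sym)
    target = float(r.n_electrons)
    clipped = np.clip(w, 0.0, 2.0)
    if abs(clipped.sum() - target) > 1e-13 or not np.allclose(clipped, w):
        lo = w.min() - 2.0
        hi = w.max()
        for _ in range(200):
            lam = 0.5 * (lo + hi)
            s = np.clip(w - lam, 0.0, 2.0).sum()
            if s > target:
                lo = lam
            else:
                hi = lam
        clipped = np.clip(w - 0.5 * (lo + hi), 0.0, 2.0)
        # exact trace: distribute the residual over unsaturated orbitals
        free = (clipped > 1e-14) & (clipped < 2.0 - 1e-14)
        if free.any():
            clipped[free] += (target - clipped.sum()) / free.sum()
        out = r.copy()
        out.dm1 = U @ np.diag(clipped) @ U.T
        return out
    return r


def constrain_dm2(r: RDMPair) -> RDMPair:
    """Impose 2-RDM normalization and index symmetries.

    Symmetrizes over the hermitian pairs and (pq)<->(rs) exchange, rescales
    the full trace to N(N-1), and projects the partial trace onto
    (N-1) dm1 (dm1 is taken as already normalized/symmetrized).
    """
    out = r.copy()
    d = out.dm2
    d = 0.5 * (d + d.transpose(2, 3, 0, 1))      # d_pqrs = d_rspq
    d = 0.5 * (d + d.transpose(1, 0, 3, 2))      # d_pqrs = d_qpsr (real states)
    N = r.n_electrons
    full_tr = float(np.einsum("ppqq->", d))
    if N > 1 and full_tr > 0:
        d *= N * (N - 1) / full_tr
    # project the partial trace onto its exact value (N-1) dm1; the
    # correction is built symmetric so a second pass is a no-op
    n = r.n_orbitals
    ptrace = np.einsum("pqrr->pq", d)
    defect = ptrace - (N - 1) * r.dm1
    eye = np.eye(n)
    d -= (np.einsum("pq,rs->pqrs", defect, eye)
          + np.einsum("pq,rs->pqrs", eye, defect)) / n
    out.dm2 = d
    return out


def process_rdms(r: RDMPair, canonical: bool = True
                 ) -> tuple[RDMPair, NaturalOrbitalTransform | None]:
    """Full measured-RDM pipeline; skips canonicalization when requested."""
    out = normalize_dm1(r)
    out = symmetrize_dm1(out)
    out = clip_occupations(out)
    out = constrain_dm2(out)
    if canonical:
        out, transform = canonicalize(out)
        return out, transform
    return out, None
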