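"""Second-quantized fermionic operators on active-space spin orbitals.

Spin orbitals use *blocked* ordering: alpha spatial orbitals occupy modes
0..n-1 and beta orbitals modes n..2n-1.  A term is a tuple of
``(mode, is_creation)`` factors applied left to right as written, e.g.
``((p, True), (q, False))`` is ``a^dag_p a_q``.
"""

from __future__ import annotations

import numpy as np

from .active_space import ActiveHamiltonian

__all__ = ["FermionOperator", "to_spin_orbitals", "spin_summed_excitation",
           "spin_summed_pair_excitation"]


class FermionOperator:
    """Sparse linear combination of products of ladder operators."""

    __slots__ = ("n_modes", "terms")

    def __init__(self, n_modes: int,
                 terms: dict[tuple, complex] | None = None):
        self.n_modes = n_modes
        self.terms = dict(terms or {})
        for seq in self.terms:
            for mode, _ in seq:
                if not 0 <= mode < n_modes:
                    raise ValueError(f"mode {mode} out of range")

    def add_term(self, seq: tuple, coeff: complex) -> None:
        if coeff == 0.0:
            return
        self.terms[seq] = self.terms.get(seq, 0.0) + coeff

    def __add__(self, other: "FermionOperator") -> "FermionOperator":
        if self.n_modes != other.n_modes:
            raise ValueError("mode-count mismatch")
        out = FermionOperator(self.n_modes, dict(self.terms))
        for seq, c in other.terms.items():
            out.add_term(seq, c)
        return out

    def __mul__(self, scalar) -> "FermionOperator":
        return FermionOperator(
            self.n_modes, {s: c * scalar for s, c in self.terms.items()})

    __rmul__ = __mul__

    def dagger(self) -> "FermionOperator":
        out = FermionOperator(self.n_modes)
        for seq, c in self.terms.items():
            new_seq = tuple((m, not dag) for m, dag in reversed(seq))
            out.add_term(new_seq, np.conjugate(c))
        return out

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def alpha_index(p: int, n_orb: int) -> int:
    return p


def beta_index(p: int, n_orb: int) -> int:
    return p + n_orb


def to_spin_orbitals(h_act: ActiveHamiltonian) -> FermionOperator:
    """Expand an active-space Hamiltonian over blocked spin orbitals.

    H = sum_{pq,s} h_pq a^dag_ps a_qs
      + 1/2 sum_{pqrs,st} (pq|rs) a^dag_ps a^dag_rt a_st' a_qs  (chemist ERIs)

    The constant ``e_core`` is carried as a coefficient on the empty term.
    """
    n = h_act.n_active_orbitals
    nm = 2 * n
    op = FermionOperator(nm)
    op.add_term((), h_act.e_core)
    h = h_act.h_eff
    g = h_act.g_act
    for p in range(n):
        for q in range(n):
            if h[p, q] == 0.0:
                continue
            for sp_ix in (alpha_index, beta_index):
                op.add_term(((sp_ix(p, n), True), (sp_ix(q, n), False)),
                            h[p, q])
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    c = 0.5 * g[p, q, r, s]
                    if c == 0.0:
                        continue
                    for ix1 in (alpha_index, beta_index):
                        for ix2 in (alpha_index, beta_index):
                            op.add_term(((ix1(p, n), True), (ix2(r, n), True),
                                         (ix2(s, n), False), (ix1(q, n), False)),
                                        c)
    return op


def spin_summed_excitation(p: int, q: int, n_orb: int) -> FermionOperator:
    """E_pq = sum_sigma a^dag_p,sigma a_q,sigma."""
    op = FermionOperator(2 * n_orb)
    for ix in (alpha_index, beta_index):
        op.add_term(((ix(p, n_orb), True), (ix(q, n_orb), False)), 1.0)
    return op


def spin_summed_pair_excitation(p: int, q: int, r: int, s: int,
                                n_orb: int) -> FermionOperator:
    """e_pqrs = E_pq E_rs - delta_qr E_ps = sum_st a^dag_ps a^dag_rt a_st a_qs.

    Its ground-state expectation is the chemist-ordered spin-summed 2-RDM
    element d_pqrs with full trace N(N-1).
    """
    op = FermionOperator(2 * n_orb)
    for ix1 in (alpha_index, beta_index):
        for ix2 in (alpha_index, beta_index):
            op.add_term(((ix1(p, n_orb), True), (ix2(r, n_orb), True),
                         (ix2(s, n_orb), False), (ix1(q, n_orb), False)), 1.0)
    return op
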