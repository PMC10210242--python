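"""Gaussian basis sets: NWChem-format parsing, shells, normalization.

Shells are segmented-contracted Cartesian Gaussians; general contractions in
the source files (multiple coefficient columns) are split into one shell per
column, with zero-coefficient primitives pruned.  Contraction coefficients are
stored for *normalized* primitives and rescaled so that the (l,0,0) Cartesian
component of every contracted function has unit self-overlap.  Shells with
l >= 2 are used in the real-solid-harmonic (spherical) representation, which
is what gives cc-pVDZ water its 24 contracted functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

_L_OF = {"S": 0, "P": 1, "D": 2, "F": 3}
_SYM_OF_L = {v: k for k, v in _L_OF.items()}

BUNDLED_BASIS_SETS = ("sto-3g", "6-31g", "cc-pvdz")


class BasisError(ValueError):
    """Unknown basis, unsupported element, or malformed basis file."""


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(l: int, alpha: float) -> float:
    """Norm constant of the Cartesian primitive x^l exp(-alpha r^2)."""
    return ((2.0 * alpha / np.pi) ** 0.75
            * (4.0 * alpha) ** (l / 2.0)
            / np.sqrt(_double_factorial(2 * l - 1)))


@dataclass
class Shell:
    """One segmented-contracted shell on one atom."""

    l: int
    center: np.ndarray           # (3,) Bohr
    exps: np.ndarray             # (nprim,)
    coefs: np.ndarray            # (nprim,) including primitive norms
    atom_index: int = -1

    @property
    def n_cart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    @property
    def n_sph(self) -> int:
        return 2 * self.l + 1


def _normalize_contraction(l: int, exps: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Fold primitive norms into coefficients and normalize the (l,0,0) AO."""
    c = coefs * np.array([primitive_norm(l, a) for a in exps])
    # Self-overlap of the contracted (l,0,0) Cartesian function.
    s = 0.0
    for ci, ai in zip(c, exps):
        for cj, aj in zip(c, exps):
            p = ai + aj
            s += ci * cj * (np.pi / p) ** 1.5 * _double_factorial(2 * l - 1) / (2.0 * p) ** l
    return c / np.sqrt(s)


def parse_nwchem_basis(text: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse NWChem-format basis text into per-element shell data.

    Returns ``{element: [(l, exps, raw_coefs), ...]}`` with general
    contractions split into segmented shells and zero coefficients pruned.
    """
    shells: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    element = None
    l_chars: str | None = None
    rows: list[list[float]] = []

    def flush():
        nonlocal rows
        if element is None or l_chars is None or not rows:
            rows = []
            return
        mat = np.array(rows)
        exps = mat[:, 0]
        coef_cols = mat[:, 1:]
        if l_chars == "SP":  # Pople split: one column per angular momentum
            for col, lc in enumerate(l_chars):
                keep = np.abs(coef_cols[:, col]) > 0
                shells.setdefault(element, []).append(
                    (_L_OF[lc], exps[keep], coef_cols[keep, col]))
        else:
            l = _L_OF[l_chars]
            for col in range(coef_cols.shape[1]):
                keep = np.abs(coef_cols[:, col]) > 0
                if keep.any():
                    shells.setdefault(element, []).append(
                        (l, exps[keep], coef_cols[keep, col]))
        rows = []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        up = line.upper()
        if up.startswith(("BASIS", "END")):
            flush()
            element = None
            continue
        parts = line.split()
        if parts[0][0].isalpha():
            flush()
            element = parts[0].capitalize()
            l_chars = parts[1].upper()
            if l_chars not in _L_OF and l_chars != "SP":
                raise BasisError(f"unsupported shell type {l_chars!r}")
            continue
        try:
            rows.append([float(p.replace("D", "E").replace("d", "e"))
                         for p in parts])
        except ValueError:
            raise BasisError(f"unparsable basis line: {raw!r}") from None
    flush()
    if not shells:
        raise BasisError("no shells found in basis input")
    return shells


def _basis_text(name: str) -> str:
    key = name.lower()
    if key in BUNDLED_BASIS_SETS:
        ref = resources.files("quantumcas.data").joinpath(f"basis/{key}.nw")
        return ref.read_text()
    try:
        with open(name) as fh:  # treat as a path to a user basis file
            return fh.read()
    except OSError:
        raise BasisError(
            f"unknown basis {name!r}: not one of {BUNDLED_BASIS_SETS} "
            "and not a readable NWChem-format file"
        ) from None


class BasisSet:
    """All shells for a molecule, with AO offsets in the spherical basis."""

    def __init__(self, shells: list[Shell], name: str = ""):
        self.name = name
        self.shells = shells
        self.offsets = []
        n = 0
        for sh in shells:
            self.offsets.append(n)
            n += sh.n_sph
        self.n_basis = n

    @classmethod
    def build(cls, geometry, basis_name: str) -> "BasisSet":
        per_element = parse_nwchem_basis(_basis_text(basis_name))
        shells = []
        for iat, (sym, *_xyz) in enumerate(geometry.atoms):
            if sym not in per_element:
                raise BasisError(f"basis {basis_name!r} has no element {sym}")
            for l, exps, coefs in per_element[sym]:
                shells.append(Shell(
                    l=l,
                    center=geometry.coords_bohr[iat].copy(),
                    exps=np.asarray(exps, float),
                    coefs=_normalize_contraction(l, np.asarray(exps, float),
                                                 np.asarray(coefs, float)),
                    atom_index=iat,
                ))
        return cls(shells, name=basis_name)

    def count_basis_functions(self) -> int:
        return self.n_basis


def count_basis_functions(geometry, basis_name: str) -> int:
    """Number of contracted (spherical) AO basis functions for a molecule."""
    return BasisSet.build(geometry, basis_name).n_basis
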