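"""Molecular geometries: XYZ parsing, element bookkeeping, nuclear repulsion.

Coordinates are read in Ångström and converted to Bohr internally; all
energies are in Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092

# Nuclear charges for the elements this package supports out of the box.
ELEMENT_Z = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
}


class GeometryError(ValueError):
    """Malformed geometry input (bad XYZ text, unknown element, ...)."""


@dataclass
class Geometry:
    """A molecule: element symbols, Cartesian coordinates (Å), charge, spin.

    Parameters
    ----------
    atoms
        List of ``(symbol, x, y, z)`` tuples with coordinates in Ångström.
    charge
        Total molecular charge.
    spin_multiplicity
        2S+1.  Must be consistent with the electron-count parity.
    """

    atoms: list[tuple[str, float, float, float]]
    charge: int = 0
    spin_multiplicity: int = 1
    comment: str = ""
    _coords_bohr: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for sym, *_ in self.atoms:
            if sym not in ELEMENT_Z:
                raise GeometryError(f"unknown element symbol {sym!r}")
        if self.spin_multiplicity < 1:
            raise GeometryError("spin multiplicity must be >= 1")
        if (self.n_electrons - (self.spin_multiplicity - 1)) % 2 != 0:
            raise GeometryError(
                f"multiplicity {self.spin_multiplicity} inconsistent with "
                f"{self.n_electrons} electrons"
            )
        coords = np.array([[x, y, z] for _, x, y, z in self.atoms], float)
        self._coords_bohr = coords * BOHR_PER_ANGSTROM

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> list[str]:
        return [a[0] for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([ELEMENT_Z[s] for s in self.symbols], float)

    @property
    def coords_bohr(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in Bohr."""
        return self._coords_bohr

    @property
    def n_electrons(self) -> int:
        return int(sum(ELEMENT_Z[s] for s in self.symbols)) - self.charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.spin_multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    def nuclear_repulsion(self) -> float:
        """Coulomb repulsion between the nuclei, in Hartree."""
        e = 0.0
        z = self.charges
        r = self.coords_bohr
        for i in range(self.n_atoms):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def to_xyz(self) -> str:
        lines = [str(self.n_atoms), self.comment]
        for sym, x, y, z in self.atoms:
            lines.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
        return "\n".join(lines) + "\n"


def parse_xyz(text: str, charge: int = 0, spin_multiplicity: int = 1) -> Geometry:
    """Parse standard XYZ text (count line, comment line, atom lines)."""
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise GeometryError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise GeometryError(f"bad atom-count line: {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < n:
        raise GeometryError(f"header promises {n} atoms, found {len(atom_lines)}")
    atoms = []
    for ln in atom_lines[:n]:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"bad atom line: {ln!r}")
        sym = parts[0].capitalize()
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise GeometryError(f"unparsable coordinate on line: {ln!r}") from None
        atoms.append((sym, x, y, z))
    return Geometry(atoms, charge=charge, spin_multiplicity=spin_multiplicity,
                    comment=comment)


def load_xyz(path, charge: int = 0, spin_multiplicity: int = 1) -> Geometry:
    with open(path) as fh:
        return parse_xyz(fh.read(), charge, spin_multiplicity)


def bundled_geometry(name: str, charge: int = 0,
                     spin_multiplicity: int = 1) -> Geometry:
    """Load one of the geometries shipped with the package (e.g. ``co_1.54``)."""
    ref = resources.files("quantumcas.data").joinpath(f"geometries/{name}.xyz")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise GeometryError(f"no bundled geometry named {name!r}") from None
    return parse_xyz(text, charge, spin_multiplicity)
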