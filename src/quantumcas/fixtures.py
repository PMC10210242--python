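"""Synthetic active-space Hamiltonian fixtures with exact sidecar values.

Three generator families:

* ``random_hamiltonian`` — dense random one-/two-body integrals with the
  full 8-fold permutational symmetry imposed; exercises every code path
  with no molecular structure.
* ``hubbard_like`` — a 1D chain with nearest-neighbour hopping t and
  on-site repulsion U (U/t = 4 by default), the textbook strong-correlation
  toy model.
* ``stretched_diatomic`` — an H2-like minimal-basis pair computed from the
  package's own integral engine at a stretched bond, giving a physically
  meaningful 2-orbital CAS.

Every fixture is reproducible from its seed, and the sidecar carries the
exact sector ground energy and natural occupations from the exact solver.
"""

from __future__ import annotations

import json

import numpy as np

from .active_space import ActiveHamiltonian
from .exact import solve_active_hamiltonian
from .fcidump import write_fcidump

__all__ = ["generate_fixture", "random_hamiltonian", "hubbard_like",
           "stretched_diatomic"]


def _symmetrize_g(g: np.ndarray) -> np.ndarray:
    g = g + g.transpose(1, 0, 2, 3)
    g = g + g.transpose(0, 1, 3, 2)
    g = g + g.transpose(2, 3, 0, 1)
    return g / 8.0


def random_hamiltonian(n_orb: int, n_elec: int, seed: int,
                       scale: float = 1.0) -> ActiveHamiltonian:
    rng = np.random.default_rng(seed)
    h = rng.normal(scale=scale, size=(n_orb, n_orb))
    h = 0.5 * (h + h.T)
    g = _symmetrize_g(rng.normal(scale=scale * 0.5, size=(n_orb,) * 4))
    sz2 = n_elec % 2
    return ActiveHamiltonian(h_eff=h, g_act=g,
                             e_core=float(rng.normal()),
                             n_active_electrons=n_elec, sz2=sz2)


def hubbard_like(n_orb: int, n_elec: int, seed: int = 0, t: float = 1.0,
                 u: float = 4.0) -> ActiveHamiltonian:
    h = np.zeros((n_orb, n_orb))
    for i in range(n_orb - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    g = np.zeros((n_orb,) * 4)
    for i in range(n_orb):
        g[i, i, i, i] = u
    sz2 = n_elec % 2
    return ActiveHamiltonian(h_eff=h, g_act=g, e_core=0.0,
                             n_active_electrons=n_elec, sz2=sz2)


def stretched_diatomic(bond_length: float = 1.5,
                       seed: int = 0) -> ActiveHamiltonian:
    """Minimal-basis H2 at a stretched bond from the in-repo integral engine."""
    from .active_space import build_active_hamiltonian, select_active_space
    from .geometry import Geometry
    from .integrals import compute_ao_integrals
    from .scf import run_hf

    geom = Geometry([("H", 0.0, 0.0, 0.0), ("H", 0.0, 0.0, bond_length)])
    ints = compute_ao_integrals(geom, "sto-3g")
    scf = run_hf(ints, geom)
    act = select_active_space(scf, 2, [0, 1])
    return build_active_hamiltonian(ints, scf, act)


_KINDS = {"random_hamiltonian": random_hamiltonian,
          "hubbard_like": hubbard_like}


def generate_fixture(kind: str, size: int, seed: int,
                     out_prefix=None, n_elec: int | None = None):
    """Build a fixture Hamiltonian plus an exact-values sidecar.

    Returns ``(ActiveHamiltonian, sidecar_dict)``; when ``out_prefix`` is
    given, writes ``<prefix>.fcidump`` and ``<prefix>.json``.
    """
    if size > 6:
        raise ValueError("fixtures are capped at 6 orbitals")
    if kind == "stretched_diatomic":
        ham = stretched_diatomic(bond_length=1.0 + 0.1 * (seed % 10))
    elif kind in _KINDS:
        ham = _KINDS[kind](size, n_elec if n_elec is not None else size, seed)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    energy, _, rdms = solve_active_hamiltonian(ham)
    sidecar = {
        "kind": kind,
        "seed": seed,
        "n_orbitals": ham.n_active_orbitals,
        "n_electrons": ham.n_active_electrons,
        "sz2": ham.sz2,
        "exact_ground_energy": energy,
        "natural_occupations": rdms.occupations().tolist(),
    }
    if out_prefix is not None:
        write_fcidump(ham, f"{out_prefix}.fcidump")
        with open(f"{out_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
    return ham, sidecar
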