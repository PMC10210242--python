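"""FCIDUMP reader/writer (Molpro dialect) for active-space Hamiltonians.

Format: ``&FCI NORB=n,NELEC=m,MS2=s`` header, then one value per line with
four 1-based orbital indices — two-electron integrals (ij|kl) in chemist
notation with 8-fold permutational symmetry (only canonical index quadruples
are written), one-electron integrals as ``value i j 0 0``, and the core
energy on the ``0 0 0 0`` line.  Values are written with 17 significant
digits so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import re

import numpy as np

from .active_space import ActiveHamiltonian

__all__ = ["write_fcidump", "read_fcidump", "fcidump_str", "parse_fcidump"]


class FCIDUMPError(ValueError):
    pass


def fcidump_str(ham: ActiveHamiltonian) -> str:
    n = ham.n_active_orbitals
    lines = [
        f" &FCI NORB={n},NELEC={ham.n_active_electrons},MS2={ham.sz2},",
        "  ORBSYM=" + ",".join(["1"] * n) + ",",
        "  ISYM=1,",
        " &END",
    ]

    def fmt(v, i, j, k, l):
        return f"{v:24.17E} {i:4d} {j:4d} {k:4d} {l:4d}"

    for i in range(n):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    v = ham.g_act[i, j, k, l]
                    if v != 0.0:
                        lines.append(fmt(v, i + 1, j + 1, k + 1, l + 1))
    for i in range(n):
        for j in range(i + 1):
            v = ham.h_eff[i, j]
            if v != 0.0:
                lines.append(fmt(v, i + 1, j + 1, 0, 0))
    lines.append(fmt(ham.e_core, 0, 0, 0, 0))
    return "\n".join(lines) + "\n"


def write_fcidump(ham: ActiveHamiltonian, path) -> None:
    with open(path, "w") as fh:
        fh.write(fcidump_str(ham))


def parse_fcidump(text: str) -> ActiveHamiltonian:
    header_match = re.search(r"&FCI(.*?)(?:&END|/)", text,
                             re.DOTALL | re.IGNORECASE)
    if not header_match:
        raise FCIDUMPError("missing &FCI header")
    header = header_match.group(1)

    def get_int(key, default=None):
        m = re.search(rf"{key}\s*=\s*(-?\d+)", header, re.IGNORECASE)
        if m:
            return int(m.group(1))
        if default is None:
            raise FCIDUMPError(f"header lacks {key}")
        return default

    n = get_int("NORB")
    nelec = get_int("NELEC")
    ms2 = get_int("MS2", 0)
    h = np.zeros((n, n))
    g = np.zeros((n, n, n, n))
    e_core = 0.0
    body = text[header_match.end():]
    for line in body.splitlines():
        parts = line.split()
        if len(parts) != 5:
            if parts:
                raise FCIDUMPError(f"bad integral line: {line!r}")
            continue
        v = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(p) for p in parts[1:])
        if i == j == k == l == 0:
            e_core = v
        elif k == l == 0:
            h[i - 1, j - 1] = v
            h[j - 1, i - 1] = v
        else:
            for a, b, c, d in _eightfold(i - 1, j - 1, k - 1, l - 1):
                g[a, b, c, d] = v
    return ActiveHamiltonian(h_eff=h, g_act=g, e_core=e_core,
                             n_active_electrons=nelec, sz2=ms2)


def _eightfold(i, j, k, l):
    return {(i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
            (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i)}


def read_fcidump(path) -> ActiveHamiltonian:
    with open(path) as fh:
        return parse_fcidump(fh.read())
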