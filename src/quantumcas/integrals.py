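"""AO integrals over contracted Gaussians (McMurchie–Davidson scheme).

Computes overlap, kinetic, nuclear-attraction and electron-repulsion
integrals for s/p/d shells, in the real-spherical-harmonic AO basis.
Hermite expansion coefficients and Hermite Coulomb integrals follow the
standard McMurchie–Davidson recursions; the Boys function is evaluated by
a downward-stable series for small arguments and upward recursion for
large ones.  The primitive loops are JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .basis import BasisSet
from .geometry import Geometry

__all__ = ["AOIntegrals", "compute_ao_integrals"]


@dataclass
class AOIntegrals:
    """AO-basis integral blocks for one molecule/basis combination.

    ``eri`` is stored as the full 4-index tensor in chemist notation
    (pq|rs) with its 8-fold permutational symmetry explicit.
    """

    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear_attraction: np.ndarray
    eri: np.ndarray
    nuclear_repulsion: float
    n_basis: int

    @property
    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic + self.nuclear_attraction


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _boys(m_max, T, out):
    if T < 1e-13:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if T > 30.0:
        # upward recursion, stable for large T
        out[0] = 0.5 * np.sqrt(np.pi / T)
        emt = np.exp(-T)
        for m in range(m_max):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - emt) / (2.0 * T)
        return
    # series for the highest order, then downward recursion
    emt = np.exp(-T)
    denom = 2.0 * m_max + 1.0
    term = 1.0 / denom
    total = term
    for _ in range(200):
        denom += 2.0
        term *= 2.0 * T / denom
        total += term
        if term < 1e-17 * total:
            break
    out[m_max] = total * emt
    for m in range(m_max - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + emt) / (2.0 * m + 1.0)


@njit(cache=True)
def _hermite_E(imax, jmax, Q, a, b, E):
    """Hermite expansion coefficients E[i,j,t] for one Cartesian direction."""
    p = a + b
    mu = a * b / p
    E[:, :, :] = 0.0
    E[0, 0, 0] = np.exp(-mu * Q * Q)
    for i in range(1, imax + 1):
        for t in range(i + 1):
            v = 0.0
            if t > 0:
                v += E[i - 1, 0, t - 1] / (2.0 * p)
            v -= (mu * Q / a) * E[i - 1, 0, t]
            if t + 1 <= i - 1:
                v += (t + 1.0) * E[i - 1, 0, t + 1]
            E[i, 0, t] = v
    for j in range(1, jmax + 1):
        for i in range(imax + 1):
            for t in range(i + j + 1):
                v = 0.0
                if t > 0:
                    v += E[i, j - 1, t - 1] / (2.0 * p)
                v += (mu * Q / b) * E[i, j - 1, t]
                if t + 1 <= i + j - 1:
                    v += (t + 1.0) * E[i, j - 1, t + 1]
                E[i, j, t] = v
    return E


@njit(cache=True)
def _hermite_R(L, alpha, X, Y, Z, R):
    """Hermite Coulomb integrals R[t,u,v] for t+u+v <= L."""
    T = alpha * (X * X + Y * Y + Z * Z)
    F = np.empty(L + 1)
    _boys(L, T, F)
    Rn = np.zeros((L + 1, L + 1, L + 1, L + 1))
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for d in range(1, L + 1):
        for n in range(L - d + 1):
            for t in range(d + 1):
                for u in range(d - t + 1):
                    v = d - t - u
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1.0) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1.0) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1.0) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    R[:, :, :] = Rn[0]


@njit(cache=True)
def _one_electron_block(la, lb, A, B, exps_a, coefs_a, exps_b, coefs_b,
                        comps_a, comps_b, atom_coords, atom_charges,
                        S, T, V):
    """Contracted overlap/kinetic/nuclear blocks for one shell pair."""
    na = comps_a.shape[0]
    nb = comps_b.shape[0]
    S[:, :] = 0.0
    T[:, :] = 0.0
    V[:, :] = 0.0
    Lmax = la + lb
    Ex = np.zeros((la + 1, lb + 3, la + lb + 3))
    Ey = np.zeros((la + 1, lb + 3, la + lb + 3))
    Ez = np.zeros((la + 1, lb + 3, la + lb + 3))
    R = np.zeros((Lmax + 1, Lmax + 1, Lmax + 1))
    for ia in range(exps_a.shape[0]):
        a = exps_a[ia]
        ca = coefs_a[ia]
        for ib in range(exps_b.shape[0]):
            b = exps_b[ib]
            cb = coefs_b[ib]
            p = a + b
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            # j+2 needed for the kinetic-energy shifts
            _hermite_E(la, lb + 2, A[0] - B[0], a, b, Ex)
            _hermite_E(la, lb + 2, A[1] - B[1], a, b, Ey)
            _hermite_E(la, lb + 2, A[2] - B[2], a, b, Ez)
            pref = (np.pi / p) ** 1.5
            cc = ca * cb
            for ka in range(na):
                ax, ay, az = comps_a[ka, 0], comps_a[ka, 1], comps_a[ka, 2]
                for kb in range(nb):
                    bx, by, bz = comps_b[kb, 0], comps_b[kb, 1], comps_b[kb, 2]
                    sx = Ex[ax, bx, 0]
                    sy = Ey[ay, by, 0]
                    sz = Ez[az, bz, 0]
                    S[ka, kb] += cc * pref * sx * sy * sz
                    # kinetic via angular-momentum shifts on b
                    tx = -2.0 * b * b * Ex[ax, bx + 2, 0] \
                        + b * (2.0 * bx + 1.0) * Ex[ax, bx, 0]
                    if bx >= 2:
                        tx -= 0.5 * bx * (bx - 1.0) * Ex[ax, bx - 2, 0]
                    ty = -2.0 * b * b * Ey[ay, by + 2, 0] \
                        + b * (2.0 * by + 1.0) * Ey[ay, by, 0]
                    if by >= 2:
                        ty -= 0.5 * by * (by - 1.0) * Ey[ay, by - 2, 0]
                    tz = -2.0 * b * b * Ez[az, bz + 2, 0] \
                        + b * (2.0 * bz + 1.0) * Ez[az, bz, 0]
                    if bz >= 2:
                        tz -= 0.5 * bz * (bz - 1.0) * Ez[az, bz - 2, 0]
                    T[ka, kb] += cc * pref * (tx * sy * sz + sx * ty * sz
                                              + sx * sy * tz)
            for iat in range(atom_coords.shape[0]):
                _hermite_R(Lmax, p, Px - atom_coords[iat, 0],
                           Py - atom_coords[iat, 1],
                           Pz - atom_coords[iat, 2], R)
                zc = atom_charges[iat]
                for ka in range(na):
                    ax, ay, az = comps_a[ka, 0], comps_a[ka, 1], comps_a[ka, 2]
                    for kb in range(nb):
                        bx, by, bz = comps_b[kb, 0], comps_b[kb, 1], comps_b[kb, 2]
                        acc = 0.0
                        for t in range(ax + bx + 1):
                            et = Ex[ax, bx, t]
                            if et == 0.0:
                                continue
                            for u in range(ay + by + 1):
                                eu = Ey[ay, by, u]
                                if eu == 0.0:
                                    continue
                                for v in range(az + bz + 1):
                                    acc += et * eu * Ez[az, bz, v] * R[t, u, v]
                        V[ka, kb] -= cc * zc * (2.0 * np.pi / p) * acc


@njit(cache=True)
def _eri_quartet(la, lb, lc, ld, A, B, C, D,
                 ea, ca, eb, cb, ec, cc_, ed, cd,
                 comps_a, comps_b, comps_c, comps_d, out):
    """Contracted Cartesian ERIs (ab|cd) for one shell quartet."""
    na, nb = comps_a.shape[0], comps_b.shape[0]
    nc, nd = comps_c.shape[0], comps_d.shape[0]
    out[:, :, :, :] = 0.0
    L1 = la + lb
    L2 = lc + ld
    Lmax = L1 + L2
    E1x = np.zeros((la + 1, lb + 1, L1 + 1))
    E1y = np.zeros((la + 1, lb + 1, L1 + 1))
    E1z = np.zeros((la + 1, lb + 1, L1 + 1))
    E2x = np.zeros((lc + 1, ld + 1, L2 + 1))
    E2y = np.zeros((lc + 1, ld + 1, L2 + 1))
    E2z = np.zeros((lc + 1, ld + 1, L2 + 1))
    R = np.zeros((Lmax + 1, Lmax + 1, Lmax + 1))
    herm2 = np.zeros((nc, nd, L2 + 1, L2 + 1, L2 + 1))
    for i in range(ea.shape[0]):
        a = ea[i]
        for j in range(eb.shape[0]):
            b = eb[j]
            p = a + b
            cab = ca[i] * cb[j]
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            _hermite_E(la, lb, A[0] - B[0], a, b, E1x)
            _hermite_E(la, lb, A[1] - B[1], a, b, E1y)
            _hermite_E(la, lb, A[2] - B[2], a, b, E1z)
            for k in range(ec.shape[0]):
                c = ec[k]
                for m in range(ed.shape[0]):
                    d = ed[m]
                    q = c + d
                    ccd = cc_[k] * cd[m]
                    Qx = (c * C[0] + d * D[0]) / q
                    Qy = (c * C[1] + d * D[1]) / q
                    Qz = (c * C[2] + d * D[2]) / q
                    _hermite_E(lc, ld, C[0] - D[0], c, d, E2x)
                    _hermite_E(lc, ld, C[1] - D[1], c, d, E2y)
                    _hermite_E(lc, ld, C[2] - D[2], c, d, E2z)
                    alpha = p * q / (p + q)
                    _hermite_R(Lmax, alpha, Px - Qx, Py - Qy, Pz - Qz, R)
                    pref = (cab * ccd * 2.0 * np.pi ** 2.5
                            / (p * q * np.sqrt(p + q)))
                    # contract the ket side into Hermite space first
                    herm2[:, :, :, :, :] = 0.0
                    for kc in range(nc):
                        cx, cy, cz = comps_c[kc, 0], comps_c[kc, 1], comps_c[kc, 2]
                        for kd in range(nd):
                            dx, dy, dz = comps_d[kd, 0], comps_d[kd, 1], comps_d[kd, 2]
                            for t2 in range(cx + dx + 1):
                                e2t = E2x[cx, dx, t2]
                                if e2t == 0.0:
                                    continue
                                for u2 in range(cy + dy + 1):
                                    e2u = E2y[cy, dy, u2]
                                    if e2u == 0.0:
                                        continue
                                    for v2 in range(cz + dz + 1):
                                        sign = 1.0 if (t2 + u2 + v2) % 2 == 0 else -1.0
                                        herm2[kc, kd, t2, u2, v2] = \
                                            sign * e2t * e2u * E2z[cz, dz, v2]
                    for ka in range(na):
                        ax, ay, az = comps_a[ka, 0], comps_a[ka, 1], comps_a[ka, 2]
                        for kb in range(nb):
                            bx, by, bz = comps_b[kb, 0], comps_b[kb, 1], comps_b[kb, 2]
                            for kc in range(nc):
                                cx, cy, cz = comps_c[kc, 0], comps_c[kc, 1], comps_c[kc, 2]
                                for kd in range(nd):
                                    dx, dy, dz = comps_d[kd, 0], comps_d[kd, 1], comps_d[kd, 2]
                                    acc = 0.0
                                    for t1 in range(ax + bx + 1):
                                        e1t = E1x[ax, bx, t1]
                                        if e1t == 0.0:
                                            continue
                                        for u1 in range(ay + by + 1):
                                            e1u = E1y[ay, by, u1]
                                            if e1u == 0.0:
                                                continue
                                            for v1 in range(az + bz + 1):
                                                e1 = e1t * e1u * E1z[az, bz, v1]
                                                if e1 == 0.0:
                                                    continue
                                                s = 0.0
                                                for t2 in range(cx + dx + 1):
                                                    for u2 in range(cy + dy + 1):
                                                        for v2 in range(cz + dz + 1):
                                                            h2 = herm2[kc, kd, t2, u2, v2]
                                                            if h2 != 0.0:
                                                                s += h2 * R[t1 + t2,
                                                                            u1 + u2,
                                                                            v1 + v2]
                                                acc += e1 * s
                                    out[ka, kb, kc, kd] += pref * acc


# ---------------------------------------------------------------------------
# python drivers
# ---------------------------------------------------------------------------

def _cart_components(l: int) -> np.ndarray:
    comps = []
    for i in range(l, -1, -1):
        for j in range(l - i, -1, -1):
            comps.append((i, j, l - i - j))
    return np.array(comps, dtype=np.int64)


_SQRT3 = np.sqrt(3.0)

# cart -> real-spherical transforms; Cartesian columns in lexicographic order
# (xx, xy, xz, yy, yz, zz for d), coefficients for (l,0,0)-normalized shells.
_CART2SPH = {
    0: np.array([[1.0]]),
    1: np.eye(3),
    2: np.array([
        [0.0, _SQRT3, 0.0, 0.0, 0.0, 0.0],          # m = -2  (xy)
        [0.0, 0.0, 0.0, 0.0, _SQRT3, 0.0],          # m = -1  (yz)
        [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],           # m =  0  (3z^2-r^2)
        [0.0, 0.0, _SQRT3, 0.0, 0.0, 0.0],          # m = +1  (xz)
        [_SQRT3 / 2, 0.0, 0.0, -_SQRT3 / 2, 0.0, 0.0],  # m = +2 (x^2-y^2)
    ]),
}


def compute_ao_integrals(geometry: Geometry, basis_name: str) -> AOIntegrals:
    """All AO integrals for a molecule in the named basis (spherical AOs)."""
    basis = basis_name if isinstance(basis_name, BasisSet) \
        else BasisSet.build(geometry, basis_name)
    shells = basis.shells
    nsh = len(shells)
    for sh in shells:
        if sh.l > 2:
            raise NotImplementedError("integrals implemented for l <= 2 (s,p,d)")
    comps = [_cart_components(sh.l) for sh in shells]
    ncart_of = [c.shape[0] for c in comps]
    cart_off = np.concatenate([[0], np.cumsum(ncart_of)]).astype(int)
    ncart = int(cart_off[-1])
    nsph = basis.n_basis

    atom_coords = geometry.coords_bohr
    atom_charges = geometry.charges

    S = np.zeros((ncart, ncart))
    T = np.zeros((ncart, ncart))
    V = np.zeros((ncart, ncart))
    for isha in range(nsh):
        sa = shells[isha]
        for ishb in range(isha + 1):
            sb = shells[ishb]
            bS = np.zeros((ncart_of[isha], ncart_of[ishb]))
            bT = np.zeros_like(bS)
            bV = np.zeros_like(bS)
            _one_electron_block(sa.l, sb.l, sa.center, sb.center,
                                sa.exps, sa.coefs, sb.exps, sb.coefs,
                                comps[isha], comps[ishb],
                                atom_coords, atom_charges, bS, bT, bV)
            ra = slice(cart_off[isha], cart_off[isha + 1])
            rb = slice(cart_off[ishb], cart_off[ishb + 1])
            for M, B_ in ((S, bS), (T, bT), (V, bV)):
                M[ra, rb] = B_
                if isha != ishb:
                    M[rb, ra] = B_.T

    eri = np.zeros((ncart, ncart, ncart, ncart))
    pairs = [(i, j) for i in range(nsh) for j in range(i + 1)]
    for ip, (i, j) in enumerate(pairs):
        for k, l in pairs[: ip + 1]:
            si, sj, sk, sl = shells[i], shells[j], shells[k], shells[l]
            block = np.zeros((ncart_of[i], ncart_of[j],
                              ncart_of[k], ncart_of[l]))
            _eri_quartet(si.l, sj.l, sk.l, sl.l,
                         si.center, sj.center, sk.center, sl.center,
                         si.exps, si.coefs, sj.exps, sj.coefs,
                         sk.exps, sk.coefs, sl.exps, sl.coefs,
                         comps[i], comps[j], comps[k], comps[l], block)
            ri = slice(cart_off[i], cart_off[i + 1])
            rj = slice(cart_off[j], cart_off[j + 1])
            rk = slice(cart_off[k], cart_off[k + 1])
            rl = slice(cart_off[l], cart_off[l + 1])
            eri[ri, rj, rk, rl] = block
            eri[rj, ri, rk, rl] = block.transpose(1, 0, 2, 3)
            eri[ri, rj, rl, rk] = block.transpose(0, 1, 3, 2)
            eri[rj, ri, rl, rk] = block.transpose(1, 0, 3, 2)
            eri[rk, rl, ri, rj] = block.transpose(2, 3, 0, 1)
            eri[rl, rk, ri, rj] = block.transpose(3, 2, 0, 1)
            eri[rk, rl, rj, ri] = block.transpose(2, 3, 1, 0)
            eri[rl, rk, rj, ri] = block.transpose(3, 2, 1, 0)

    # block cart -> spherical transformation
    C = np.zeros((nsph, ncart))
    for ish, sh in enumerate(shells):
        c2s = _CART2SPH[sh.l]
        r0 = basis.offsets[ish]
        C[r0:r0 + sh.n_sph, cart_off[ish]:cart_off[ish + 1]] = c2s

    S_s = C @ S @ C.T
    T_s = C @ T @ C.T
    V_s = C @ V @ C.T
    eri_s = np.einsum("pqrs,ip,jq,kr,ls->ijkl", eri, C, C, C, C, optimize=True)

    return AOIntegrals(overlap=S_s, kinetic=T_s, nuclear_attraction=V_s,
                       eri=eri_s, nuclear_repulsion=geometry.nuclear_repulsion(),
                       n_basis=nsph)
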