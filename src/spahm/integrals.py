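"""Gaussian integrals over pure (spherical) contracted Gaussians.

A self-contained McMurchie-Davidson engine: Hermite expansion coefficients,
Hermite Coulomb tensors with the Boys function, and shell-pair drivers for

* overlap, kinetic, nuclear attraction,
* two-, three- and four-center Coulomb repulsion integrals,
* basis-function values on real-space grids.

All basis functions are real solid-harmonic Gaussians (never Cartesian); each
contracted function is normalized to unit self-overlap.  Lengths are Bohr and
energies Hartree throughout.

Scale note: the engine is written for the molecule sizes this package targets
(guess Hamiltonians in minimal bases, fitting bases on a handful of centers);
shell-pair loops are plain Python with numpy inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, hyp1f1

from .harmonics import cartesian_monomials, eval_solid_harmonics, sph_coef_matrix

__all__ = ["PlacedShell", "overlap", "kinetic", "nuclear_attraction",
           "eri2c", "eri3c", "eri4c", "eval_on_grid", "n_ao"]


# ----------------------------------------------------------------- shells

@dataclass(frozen=True)
class PlacedShell:
    """A contracted solid-harmonic shell at a fixed point in space (Bohr)."""

    l: int
    exps: np.ndarray
    coefs: np.ndarray                 # raw contraction coefficients
    center: np.ndarray
    _d: np.ndarray = field(init=False, repr=False)  # normalized effective coefs

    def __post_init__(self):
        exps = np.asarray(self.exps, dtype=float)
        coefs = np.asarray(self.coefs, dtype=float)
        if exps.ndim != 1 or exps.size == 0 or np.any(exps <= 0):
            raise ValueError("shell needs at least one positive exponent")
        if coefs.shape != exps.shape:
            raise ValueError("one contraction coefficient per exponent")
        object.__setattr__(self, "exps", exps)
        object.__setattr__(self, "coefs", coefs)
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))
        # unit-norm primitives, then normalize the contraction:
        # <S_lm e^{-a r^2}|S_lm e^{-b r^2}> = Gamma(l+3/2) / (2 (a+b)^{l+3/2})
        l = self.l
        lg = gammaln(l + 1.5)
        npr = np.exp(0.5 * (np.log(2.0) + (l + 1.5) * np.log(2.0 * exps) - lg))
        d = coefs * npr
        ss = np.exp(lg - np.log(2.0) - (l + 1.5) *
                    np.log(exps[:, None] + exps[None, :]))
        norm2 = d @ ss @ d
        object.__setattr__(self, "_d", d / np.sqrt(norm2))

    @property
    def nfun(self) -> int:
        return 2 * self.l + 1


def n_ao(shells) -> int:
    return sum(sh.nfun for sh in shells)


# ------------------------------------------------- Hermite E coefficients

def _e_table(i_max: int, j_max: int, a: float, b: float, AB: float) -> np.ndarray:
    """E[t, i, j] Hermite expansion coefficients for one Cartesian direction."""
    p = a + b
    mu = a * b / p
    XPA = -b / p * AB          # P - A with AB = A - B
    XPB = a / p * AB
    tmax = i_max + j_max
    E = np.zeros((tmax + 1, i_max + 1, j_max + 1))
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    for i in range(1, i_max + 1):
        for t in range(i + 1):
            v = XPA * E[t, i - 1, 0]
            if t > 0:
                v += E[t - 1, i - 1, 0] / (2.0 * p)
            if t + 1 <= tmax and t + 1 <= i - 1:
                v += (t + 1) * E[t + 1, i - 1, 0]
            E[t, i, 0] = v
    for j in range(1, j_max + 1):
        for i in range(i_max + 1):
            for t in range(i + j + 1):
                v = XPB * E[t, i, j - 1]
                if t > 0:
                    v += E[t - 1, i, j - 1] / (2.0 * p)
                if t + 1 <= i + j - 1:
                    v += (t + 1) * E[t + 1, i, j - 1]
                E[t, i, j] = v
    return E


def _boys(nmax: int, T: float) -> np.ndarray:
    n = np.arange(nmax + 1)
    return hyp1f1(n + 0.5, n + 1.5, -T) / (2.0 * n + 1.0)


def _r_tensor(tmax: int, umax: int, vmax: int, p: float, PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R^0_{tuv}(p, PC).

    The auxiliary order n is carried as a vectorized leading axis; entries
    outside the valid wedge n + t + u + v <= nmax are never consumed.
    """
    nmax = tmax + umax + vmax
    T = p * float(PC @ PC)
    F = _boys(nmax, T)
    R = np.zeros((nmax + 1, tmax + 1, umax + 1, vmax + 1))
    R[:, 0, 0, 0] = (-2.0 * p) ** np.arange(nmax + 1) * F
    for t in range(1, tmax + 1):
        hi = nmax - t + 1
        R[:hi, t, 0, 0] = PC[0] * R[1:hi + 1, t - 1, 0, 0]
        if t > 1:
            R[:hi, t, 0, 0] += (t - 1) * R[1:hi + 1, t - 2, 0, 0]
    for u in range(1, umax + 1):
        hi = nmax - u + 1
        R[:hi, :, u, 0] = PC[1] * R[1:hi + 1, :, u - 1, 0]
        if u > 1:
            R[:hi, :, u, 0] += (u - 1) * R[1:hi + 1, :, u - 2, 0]
    for w in range(1, vmax + 1):
        hi = nmax - w + 1
        R[:hi, :, :, w] = PC[2] * R[1:hi + 1, :, :, w - 1]
        if w > 1:
            R[:hi, :, :, w] += (w - 1) * R[1:hi + 1, :, :, w - 2]
    return R[0]


def _hermite_coefs(sh_a: PlacedShell, sh_b: PlacedShell, ia: int, ib: int):
    """Hermite expansion of one primitive pair for every Cartesian component pair.

    Returns (p, P, H) with H[c_a, c_b, t, u, v]: the product of Cartesian
    monomial components expanded over Hermite Gaussians Lambda_tuv at P.
    """
    a, b = sh_a.exps[ia], sh_b.exps[ib]
    p = a + b
    A, B = sh_a.center, sh_b.center
    P = (a * A + b * B) / p
    la, lb = sh_a.l, sh_b.l
    E = [_e_table(la, lb, a, b, A[d] - B[d]) for d in range(3)]
    ca = cartesian_monomials(la)
    cb = cartesian_monomials(lb)
    H = np.zeros((len(ca), len(cb), la + lb + 1, la + lb + 1, la + lb + 1))
    for x, (i1, j1, k1) in enumerate(ca):
        for y, (i2, j2, k2) in enumerate(cb):
            ex = E[0][: i1 + i2 + 1, i1, i2]
            ey = E[1][: j1 + j2 + 1, j1, j2]
            ez = E[2][: k1 + k2 + 1, k1, k2]
            H[x, y, : ex.size, : ey.size, : ez.size] = \
                ex[:, None, None] * ey[None, :, None] * ez[None, None, :]
    return p, P, H


def _sph_block(sh_a: PlacedShell, sh_b: PlacedShell, cart: np.ndarray) -> np.ndarray:
    Ba = sph_coef_matrix(sh_a.l)
    Bb = sph_coef_matrix(sh_b.l)
    return Ba @ cart @ Bb.T


# ------------------------------------------------------------ one-electron

def overlap(sh_a: PlacedShell, sh_b: PlacedShell) -> np.ndarray:
    la, lb = sh_a.l, sh_b.l
    ca, cb = cartesian_monomials(la), cartesian_monomials(lb)
    cart = np.zeros((len(ca), len(cb)))
    for ia, da in enumerate(sh_a._d):
        for ib, db in enumerate(sh_b._d):
            p, _, H = _hermite_coefs(sh_a, sh_b, ia, ib)
            cart += da * db * (np.pi / p) ** 1.5 * H[:, :, 0, 0, 0]
    return _sph_block(sh_a, sh_b, cart)


def _overlap_1d(E: np.ndarray, p: float, i: int, j: int) -> float:
    return E[0, i, j] * np.sqrt(np.pi / p)


def kinetic(sh_a: PlacedShell, sh_b: PlacedShell) -> np.ndarray:
    la, lb = sh_a.l, sh_b.l
    ca, cb = cartesian_monomials(la), cartesian_monomials(lb)
    cart = np.zeros((len(ca), len(cb)))
    for ia, da in enumerate(sh_a._d):
        for ib, db in enumerate(sh_b._d):
            a, b = sh_a.exps[ia], sh_b.exps[ib]
            p = a + b
            A, B = sh_a.center, sh_b.center
            # tables up to j+2 on the ket side
            E = [_e_table(la, lb + 2, a, b, A[d] - B[d]) for d in range(3)]

            def S(d, i, j):
                if i < 0 or j < 0:
                    return 0.0
                return _overlap_1d(E[d], p, i, j)

            def K(d, i, j):
                t = -2.0 * b * b * S(d, i, j + 2) + b * (2 * j + 1) * S(d, i, j)
                if j >= 2:
                    t -= 0.5 * j * (j - 1) * S(d, i, j - 2)
                return t

            for x, (i1, j1, k1) in enumerate(ca):
                for y, (i2, j2, k2) in enumerate(cb):
                    cart[x, y] += da * db * (
                        K(0, i1, i2) * S(1, j1, j2) * S(2, k1, k2)
                        + S(0, i1, i2) * K(1, j1, j2) * S(2, k1, k2)
                        + S(0, i1, i2) * S(1, j1, j2) * K(2, k1, k2))
    return _sph_block(sh_a, sh_b, cart)


def nuclear_attraction(sh_a: PlacedShell, sh_b: PlacedShell,
                       charges, positions) -> np.ndarray:
    """<a| sum_C -Z_C / |r - R_C| |b>."""
    la, lb = sh_a.l, sh_b.l
    ca, cb = cartesian_monomials(la), cartesian_monomials(lb)
    cart = np.zeros((len(ca), len(cb)))
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    lt = la + lb
    for ia, da in enumerate(sh_a._d):
        for ib, db in enumerate(sh_b._d):
            p, P, H = _hermite_coefs(sh_a, sh_b, ia, ib)
            for Z, C in zip(charges, positions):
                R = _r_tensor(lt, lt, lt, p, P - C)
                cart += (-Z * da * db * 2.0 * np.pi / p) * \
                    np.einsum("xytuv,tuv->xy", H, R)
    return _sph_block(sh_a, sh_b, cart)


# -------------------------------------------------------------- Coulomb

_TWO_PI_52 = 2.0 * np.pi ** 2.5


def _pair_hermites(sh_a, sh_b):
    out = []
    for ia, da in enumerate(sh_a._d):
        for ib, db in enumerate(sh_b._d):
            p, P, H = _hermite_coefs(sh_a, sh_b, ia, ib)
            out.append((da * db, p, P, H))
    return out


def _single_hermites(sh):
    """Hermite expansion of a lone shell about its own center."""
    out = []
    ca = cartesian_monomials(sh.l)
    for ia, da in enumerate(sh._d):
        a = sh.exps[ia]
        E = _e_table(sh.l, 0, a, 0.0, 0.0)
        H = np.zeros((len(ca), 1, sh.l + 1, sh.l + 1, sh.l + 1))
        for x, (i, j, k) in enumerate(ca):
            H[x, 0, : i + 1, : j + 1, : k + 1] = (
                E[: i + 1, i, 0][:, None, None]
                * E[: j + 1, j, 0][None, :, None]
                * E[: k + 1, k, 0][None, None, :])
        out.append((da, a, sh.center, H))
    return out


def _coulomb_hermite(bra, ket):
    """Contract two Hermite expansions through 1/r12."""
    blk = None
    for wa, p, P, Ha in bra:
        ta = Ha.shape[2] - 1
        for wb, q, Q, Hb in ket:
            nbx, nby = Hb.shape[0], Hb.shape[1]
            tb = Hb.shape[2] - 1
            alpha = p * q / (p + q)
            R = _r_tensor(ta + tb, ta + tb, ta + tb, alpha, P - Q)
            pref = wa * wb * _TWO_PI_52 / (p * q * np.sqrt(p + q))
            sgn = np.array([(-1.0) ** t for t in range(tb + 1)])
            Hbs = Hb * sgn[None, None, :, None, None] \
                     * sgn[None, None, None, :, None] \
                     * sgn[None, None, None, None, :]
            Rsub = R
            # sum_{tuv,TUV} Ha[.,.,tuv] Hb[.,.,TUV] (-1)^{T+U+V} R_{t+T,u+U,v+V}
            acc = np.zeros((Ha.shape[0], Ha.shape[1], nbx, nby))
            for t in range(ta + 1):
                for u in range(ta + 1):
                    for v in range(ta + 1):
                        ha = Ha[:, :, t, u, v]
                        if not np.any(ha):
                            continue
                        rsl = Rsub[t : t + tb + 1, u : u + tb + 1, v : v + tb + 1]
                        acc += np.einsum("ab,cdtuv,tuv->abcd", ha, Hbs, rsl)
            blk = pref * acc if blk is None else blk + pref * acc
    return blk


def eri2c(sh_a: PlacedShell, sh_b: PlacedShell) -> np.ndarray:
    """(a|b) two-center Coulomb metric block, spherical AOs."""
    blk = _coulomb_hermite(_single_hermites(sh_a), _single_hermites(sh_b))
    cart = blk[:, 0, :, 0]
    return _sph_block(sh_a, sh_b, cart)


def eri3c(sh_a: PlacedShell, sh_m: PlacedShell, sh_n: PlacedShell) -> np.ndarray:
    """(a|mn) three-center Coulomb block, shape (2la+1, 2lm+1, 2ln+1)."""
    return eri3c_row([sh_a], sh_m, sh_n)[0]


def eri3c_row(aux_shells, sh_m: PlacedShell, sh_n: PlacedShell):
    """(a|mn) blocks for many aux shells against one orbital pair.

    The Hermite expansion of the orbital pair is built once and reused; this
    is the driver the fitting-integral builder calls.
    """
    ket = _pair_hermites(sh_m, sh_n)
    Bm = sph_coef_matrix(sh_m.l)
    Bn = sph_coef_matrix(sh_n.l)
    out = []
    for sh_a in aux_shells:
        blk = _coulomb_hermite(_single_hermites(sh_a), ket)
        cart = blk[:, 0, :, :]
        Ba = sph_coef_matrix(sh_a.l)
        out.append(np.einsum("ax,xyz,my,nz->amn", Ba, cart, Bm, Bn,
                             optimize=True))
    return out


def eri4c(sh_a, sh_b, sh_c, sh_d) -> np.ndarray:
    """(ab|cd) four-center Coulomb block over spherical AOs."""
    blk = _coulomb_hermite(_pair_hermites(sh_a, sh_b), _pair_hermites(sh_c, sh_d))
    Bs = [sph_coef_matrix(sh.l) for sh in (sh_a, sh_b, sh_c, sh_d)]
    return np.einsum("pw,qx,ry,sz,wxyz->pqrs", Bs[0], Bs[1], Bs[2], Bs[3], blk)


# ---------------------------------------------------------------- grids

def eval_on_grid(shells, points: np.ndarray) -> np.ndarray:
    """AO values chi_mu(r) on Cartesian points (Bohr), shape (npts, nao)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("grid points must be finite")
    cols = []
    for sh in shells:
        rel = pts - sh.center
        r2 = np.einsum("pi,pi->p", rel, rel)
        rad = np.zeros(len(pts))
        for d, a in zip(sh._d, sh.exps):
            rad += d * np.exp(-a * r2)
        ang = eval_solid_harmonics(sh.l, rel)
        cols.append(rad[:, None] * ang)
    return np.hstack(cols)
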