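"""Real solid harmonics and their rotation matrices.

All angular machinery in the package goes through this module so that a single
phase/ordering convention is used everywhere: real spherical harmonics with
m = -l ... +l (Condon-Shortley absorbed, i.e. the usual "chemist's" real
harmonics: p ordering y, z, x; d ordering xy, yz, z2, xz, x2-y2).

The solid harmonic ``S_lm(r) = r^l Y_lm(theta, phi)`` is represented as a
homogeneous polynomial in (x, y, z), built from the standard two-term
recursions.  ``S_lm`` is normalized over the unit sphere,
``int |S_lm(r_hat)|^2 dOmega = 1``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "solid_harmonic_polys",
    "cartesian_monomials",
    "sph_coef_matrix",
    "eval_solid_harmonics",
    "real_wigner",
    "rotated_coeffs",
    "zrot_coeffs",
]


def _poly_add(p, q, fac=1.0):
    out = dict(p)
    for k, v in q.items():
        out[k] = out.get(k, 0.0) + fac * v
    return {k: v for k, v in out.items() if v != 0.0}


def _poly_shift(p, dx, dy, dz, fac=1.0):
    """Multiply polynomial by fac * x^dx y^dy z^dz."""
    return {(i + dx, j + dy, k + dz): fac * v for (i, j, k), v in p.items()}


def _poly_mul_r2(p, fac=1.0):
    out = {}
    for sh in ((2, 0, 0), (0, 2, 0), (0, 0, 2)):
        out = _poly_add(out, _poly_shift(p, *sh, fac=fac))
    return out


@lru_cache(maxsize=None)
def _racah_solid(l: int):
    """Racah-normalized real solid harmonics R_l^m = sqrt(4pi/(2l+1)) r^l Y_lm.

    Returns a tuple of polynomial dicts ordered m = -l ... +l.
    """
    if l == 0:
        return ({(0, 0, 0): 1.0},)
    if l == 1:
        return ({(0, 1, 0): 1.0}, {(0, 0, 1): 1.0}, {(1, 0, 0): 1.0})
    prev = _racah_solid(l - 1)          # degree l-1, m = -(l-1)..(l-1)
    prev2 = _racah_solid(l - 2)
    lm1 = l - 1

    def P(arr, m):  # m-indexed access
        off = len(arr) // 2
        return arr[m + off]

    out = {}
    # diagonal recursion for m = +-l
    f = np.sqrt((2.0 * lm1 + 1.0) / (2.0 * lm1 + 2.0))
    top = _poly_add(_poly_shift(P(prev, lm1), 1, 0, 0, f),
                    _poly_shift(P(prev, -lm1), 0, 1, 0, -f))
    bot = _poly_add(_poly_shift(P(prev, -lm1), 1, 0, 0, f),
                    _poly_shift(P(prev, lm1), 0, 1, 0, f))
    out[l] = top
    out[-l] = bot
    # vertical recursion for |m| < l
    for m in range(-(l - 1), l):
        denom = np.sqrt(float((l + m) * (l - m)))
        term = _poly_shift(P(prev, m), 0, 0, 1, (2.0 * lm1 + 1.0) / denom)
        if abs(m) <= l - 2:
            fac = np.sqrt(float((lm1 + m) * (lm1 - m))) / denom
            term = _poly_add(term, _poly_mul_r2(P(prev2, m), fac=-fac))
        out[m] = term
    return tuple(out[m] for m in range(-l, l + 1))


@lru_cache(maxsize=None)
def solid_harmonic_polys(l: int):
    """Sphere-normalized real solid harmonics S_lm, m = -l..+l, as monomial dicts."""
    scale = np.sqrt((2.0 * l + 1.0) / (4.0 * np.pi))
    return tuple({k: scale * v for k, v in p.items()} for p in _racah_solid(l))


@lru_cache(maxsize=None)
def cartesian_monomials(l: int):
    """Cartesian monomial exponent triples of degree l, fixed lexical order."""
    return tuple((i, j, l - i - j) for i in range(l, -1, -1)
                 for j in range(l - i, -1, -1))


@lru_cache(maxsize=None)
def sph_coef_matrix(l: int) -> np.ndarray:
    """Matrix B with S_lm = sum_c B[m, c] * monomial_c, shape (2l+1, n_cart).

    Monomials of degree < l never appear (solid harmonics are homogeneous).
    """
    monos = cartesian_monomials(l)
    idx = {m: c for c, m in enumerate(monos)}
    B = np.zeros((2 * l + 1, len(monos)))
    for row, poly in enumerate(solid_harmonic_polys(l)):
        for mono, v in poly.items():
            B[row, idx[mono]] = v
    return B


def eval_solid_harmonics(l: int, points: np.ndarray) -> np.ndarray:
    """Evaluate all S_lm at Cartesian points, shape (npt, 2l+1)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros((pts.shape[0], 2 * l + 1))
    for row, poly in enumerate(solid_harmonic_polys(l)):
        acc = np.zeros(pts.shape[0])
        for (i, j, k), v in poly.items():
            acc += v * pts[:, 0] ** i * pts[:, 1] ** j * pts[:, 2] ** k
        out[:, row] = acc
    return out


@lru_cache(maxsize=None)
def _sample_dirs(l: int) -> np.ndarray:
    rng = np.random.default_rng(20240116 + l)
    n = max(4 * (2 * l + 1), 16)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]


def real_wigner(l: int, U: np.ndarray) -> np.ndarray:
    """Rotation matrix W(U) of real solid harmonics: S_lm(U v) = sum_m' W[m,m'] S_lm'(v).

    U must be a proper or improper orthogonal 3x3 matrix.  W is obtained by
    solving the (overdetermined, exactly consistent) linear system on sample
    directions; this sidesteps explicit Wigner-matrix phase conventions and is
    exact to solver precision because both sides are degree-l polynomials.
    """
    U = np.asarray(U, dtype=float)
    v = _sample_dirs(l)
    A = eval_solid_harmonics(l, v)              # (n, 2l+1) values of S_lm'(v)
    b = eval_solid_harmonics(l, v @ U.T)        # S_lm(U v)
    W, *_ = np.linalg.lstsq(A, b, rcond=None)
    return W.T


def rotated_coeffs(c: np.ndarray, l: int, R: np.ndarray) -> np.ndarray:
    """Coefficients of the rotated function (R_hat f)(r) = f(R^-1 r).

    f = sum_m c_m S_lm; returns c' with (R_hat f) = sum_m c'_m S_lm.
    """
    W = real_wigner(l, np.asarray(R, dtype=float).T)  # U = R^-1 = R^T
    return W.T @ np.asarray(c, dtype=float)


def zrot_matrix(l: int, theta: float) -> np.ndarray:
    """W(Rz(theta)) in closed form (z-rotations mix only (m, -m) doublets)."""
    M = np.zeros((2 * l + 1, 2 * l + 1))
    M[l, l] = 1.0
    for m in range(1, l + 1):
        ip, im = l + m, l - m
        cos, sin = np.cos(m * theta), np.sin(m * theta)
        # W(Rz(theta)) = Z(-theta)^T with Z the coefficient-rotation matrix
        M[ip, ip] = cos
        M[ip, im] = -sin
        M[im, ip] = sin
        M[im, im] = cos
    return M


def zrot_coeffs(c: np.ndarray, l: int, phi: float) -> np.ndarray:
    """Rotation of real-harmonic coefficients about z by angle phi.

    The (m, -m) doublets rotate as 2D rotations by m*phi; m = 0 is untouched.
    """
    c = np.asarray(c, dtype=float)
    out = c.copy()
    for m in range(1, l + 1):
        ip, im = l + m, l - m
        cos, sin = np.cos(m * phi), np.sin(m * phi)
        out[ip] = cos * c[ip] - sin * c[im]
        out[im] = sin * c[ip] + cos * c[im]
    return out
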