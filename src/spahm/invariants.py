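"""Symmetry-adapted vectors from density-fitting coefficients.

The similarity between two fitted single-center densities, averaged over all
rotations (atoms) or over rotations about the bond axis (bonds), is a dot
product of per-center feature vectors:

*Atoms* — with per-l coefficient matrices ``C^l`` (shells x m) and the
same-center radial overlaps ``S^l``, the rotation-averaged squared overlap is

    int_SO(3) |<rho_A|R rho_B>|^2 dR = sum_l (2l+1)^-1 <M_A^l, M_B^l>_F,
    M^l = S^{l,1/2} C^l C^{l,T} S^{l,1/2},

so v = concat_l (2l+1)^{-1/2} vech(M^l) (off-diagonal entries scaled by
sqrt(2)) satisfies v_A.v_B = oracle exactly.  This is the SOAP-style power
spectrum of the fitted density.

*Bonds* — for z-axis rotation averaging, group the (m, -m) coefficient pairs
of the frame-intrinsic expansion into complex vectors z_m = c_m + i c_{-m}
over the combined shell index (all l >= m).  Then

    (2pi)^-1 int |<rho_AB|Rz(phi) rho_CD>|^2 dphi
        = t_0^2 + sum_{m>0} |z_m(A)^H z_m(B)|^2 / 2,

and |z^H w|^2 = <Re Z, Re W> + <Im Z, Im W> with Z = z z^H, whose real part
is symmetric and imaginary part antisymmetric.  The feature vector therefore
carries, per m > 0, BOTH a vech-packed symmetric block
S^{1/2}(c_m c_m^T + c_{-m} c_{-m}^T)S^{1/2} and a packed antisymmetric block
S^{1/2}(c_{-m} c_m^T - c_m c_{-m}^T)S^{1/2}, each weighted 1/sqrt(2); m = 0
contributes vech(S^{1/2} c_0 c_0^T S^{1/2}) with weight 1.  (A symmetric-only
construction is not an exact dot-product rewrite of the average: it drops
the determinant-like cross term; both blocks are kept here and the identity
is enforced by the SO(2) quadrature oracle test.)

Both constructions use the plain overlap metric between auxiliary functions
(the similarity is an overlap of densities); the fitting step may use a
different (Coulomb) metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .harmonics import zrot_coeffs

__all__ = ["InvariantLayout", "InvariantVector", "radial_overlap_blocks",
           "atomic_invariant_vector", "bond_invariant_vector",
           "so3_overlap_oracle", "so2_overlap_oracle",
           "simplified_bond_vector", "atomic_layout", "bond_layout"]


@dataclass(frozen=True)
class InvariantLayout:
    """Deterministic slot list of a symmetry-adapted vector.

    Atom slots: ("l", l, n, n') with n <= n' over same-l shells.
    Bond slots: ("m", m, a, b, part) with part in {"sym", "anti"}; a, b index
    the combined (shell, l >= m) list.
    """

    kind: str                  # "atom" | "bond"
    slots: tuple

    @property
    def length(self) -> int:
        return len(self.slots)


@dataclass(frozen=True)
class InvariantVector:
    values: np.ndarray
    layout: InvariantLayout
    center: object = None      # atom index or (I, J) bond pair
    spin: str = "total"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.layout.length,):
            raise ValueError("invariant vector length does not match layout")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite invariant vector")
        object.__setattr__(self, "values", v)


# ------------------------------------------------------------ radial parts

def _shell_counts(specs) -> dict:
    """{l: number of shells} preserving shell order within each l."""
    counts = {}
    for sp in specs:
        counts[sp.l] = counts.get(sp.l, 0) + 1
    return dict(sorted(counts.items()))


def radial_overlap_blocks(specs) -> dict:
    """Same-center overlap matrices {l: S^l} between normalized shells.

    S^l_{nn'} = <phi_nlm | phi_n'lm> is m-independent; cross-l blocks vanish
    by angular orthogonality and are not stored.
    """
    from .integrals import PlacedShell
    by_l = {}
    for sp in specs:
        by_l.setdefault(sp.l, []).append(
            PlacedShell(sp.l, sp.exponents, sp.contraction, np.zeros(3)))
    out = {}
    for l, shells in sorted(by_l.items()):
        n = len(shells)
        S = np.eye(n)
        lg = gammaln(l + 1.5)
        for i in range(n):
            for j in range(i + 1, n):
                di, dj = shells[i]._d, shells[j]._d
                ai, aj = shells[i].exps, shells[j].exps
                S[i, j] = S[j, i] = di @ (
                    np.exp(lg - np.log(2.0) - (l + 1.5)
                           * np.log(ai[:, None] + aj[None, :])) @ dj)
        out[l] = S
    return out


def _sqrtm_psd(S: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(S)
    return (U * np.sqrt(np.clip(w, 0.0, None))) @ U.T


def _vech(M: np.ndarray, anti: bool = False):
    """Frobenius-faithful packing: vech with sqrt(2) off-diagonal scaling,
    or the strict upper triangle of an antisymmetric matrix times sqrt(2)."""
    n = M.shape[0]
    out = []
    for i in range(n):
        for j in range(i if anti else i, n):
            if anti:
                if j == i:
                    continue
                out.append(np.sqrt(2.0) * M[i, j])
            else:
                out.append(M[i, j] if j == i else np.sqrt(2.0) * M[i, j])
    return np.asarray(out)


# ---------------------------------------------------------------- layouts

def atomic_layout(specs) -> InvariantLayout:
    slots = []
    for l, n in _shell_counts(specs).items():
        for i in range(n):
            for j in range(i, n):
                slots.append(("l", l, i, j))
    return InvariantLayout("atom", tuple(slots))


def cross_l_pair_count(specs) -> int:
    """Slot count of the documented cross-l pairing variant (all shell pairs
    within a center, not restricted to equal l).  Accounting only: the
    shipped vectors always use the same-l construction, which is the one the
    rotation-average identity holds for."""
    n = len(list(specs))
    return n * (n + 1) // 2


def bond_layout(specs) -> InvariantLayout:
    counts = _shell_counts(specs)
    lmax = max(counts) if counts else -1
    slots = []
    for m in range(lmax + 1):
        na = sum(n for l, n in counts.items() if l >= m)
        for i in range(na):
            for j in range(i, na):
                slots.append(("m", m, i, j, "sym"))
        if m > 0:
            for i in range(na):
                for j in range(i + 1, na):
                    slots.append(("m", m, i, j, "anti"))
    return InvariantLayout("bond", tuple(slots))


# ------------------------------------------------------------- atom vector

def _coef_matrices(c_by_shell: dict) -> dict:
    out = {}
    for l, C in sorted(c_by_shell.items()):
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[1] != 2 * l + 1:
            raise ValueError(f"l={l} coefficient block needs 2l+1 columns")
        out[l] = C
    return out


def atomic_invariant_vector(c_by_shell: dict, S_blocks: dict,
                            center=None, spin="total") -> InvariantVector:
    """Rotationally invariant vector of one center's fit coefficients.

    ``c_by_shell``: {l: array (n_shells_l, 2l+1)}, m ordered -l..+l.
    ``S_blocks``: {l: same-center overlap matrix}, see radial_overlap_blocks.
    """
    C = _coef_matrices(c_by_shell)
    slots = []
    vals = []
    for l in sorted(S_blocks):
        n = S_blocks[l].shape[0]
        Cl = C.get(l, np.zeros((n, 2 * l + 1)))
        if Cl.shape[0] != n:
            raise ValueError(f"l={l}: {Cl.shape[0]} shells given, "
                             f"overlap block has {n}")
        half = _sqrtm_psd(S_blocks[l])
        M = half @ (Cl @ Cl.T) @ half
        vals.append(_vech(M) / np.sqrt(2.0 * l + 1.0))
        slots.extend(("l", l, i, j) for i in range(n) for j in range(i, n))
    layout = InvariantLayout("atom", tuple(slots))
    return InvariantVector(np.concatenate(vals) if vals else np.zeros(0),
                           layout, center, spin)


def so3_overlap_oracle(cA_by_shell: dict, cB_by_shell: dict, S_blocks: dict,
                       n_euler=(14, 14, 14)) -> float:
    """Brute-force int_SO(3) |<rho_A | R rho_B>|^2 dR (normalized Haar).

    Trapezoid (periodic, hence spectrally accurate) grids in alpha and gamma,
    Gauss-Legendre in cos(beta); the rotation acts on B's coefficients
    through explicit real-harmonic rotation matrices.
    """
    from .harmonics import real_wigner, zrot_matrix
    CA = _coef_matrices(cA_by_shell)
    CB = _coef_matrices(cB_by_shell)
    ls = [l for l in sorted(S_blocks) if l in CA and l in CB]
    G = {l: CA[l].T @ S_blocks[l] @ CB[l] for l in ls}
    na, nb, ng = n_euler
    alphas = 2.0 * np.pi * np.arange(na) / na
    gammas = 2.0 * np.pi * np.arange(ng) / ng
    xb, wb = np.polynomial.legendre.leggauss(nb)
    betas = np.arccos(xb)
    # Rotation R = Rz(alpha) Ry(beta) Rz(gamma); the coefficient matrix of B
    # transforms as B @ W(R^-1) with W a group homomorphism, so only the
    # W(Ry(-beta)) factors need a generic construction.
    Wz_a = {l: [zrot_matrix(l, -a) for a in alphas] for l in ls}
    Wz_g = {l: [zrot_matrix(l, -g) for g in gammas] for l in ls}
    total = 0.0
    for beta, wbeta in zip(betas, wb):
        Ry = np.array([[np.cos(beta), 0, -np.sin(beta)], [0, 1.0, 0],
                       [np.sin(beta), 0, np.cos(beta)]])  # Ry(-beta)
        Wy = {l: real_wigner(l, Ry) for l in ls}
        for ig in range(ng):
            half = {l: Wz_g[l][ig] @ Wy[l] for l in ls}
            for ia in range(na):
                ov = sum(np.einsum("mk,km->", G[l],
                                   half[l] @ Wz_a[l][ia]) for l in ls)
                total += wbeta * ov * ov
    return total / (2.0 * na * ng)


# ------------------------------------------------------------- bond vector

def _combined_blocks(c_by_shell: dict, S_blocks: dict):
    """Per |m|: (S^m)^{1/2}-transformed u_m, u_{-m} over the combined index.

    The combined index runs over (l ascending, shell order) restricted to
    l >= m; S^m is block diagonal in l (same-center angular orthogonality).
    """
    C = {l: np.atleast_2d(np.asarray(v, dtype=float))
         for l, v in c_by_shell.items()}
    ls = sorted(S_blocks)
    lmax = max(ls)
    halves = {l: _sqrtm_psd(S_blocks[l]) for l in ls}
    out = []
    for m in range(lmax + 1):
        up, um = [], []
        for l in ls:
            if l < m:
                continue
            n = S_blocks[l].shape[0]
            Cl = C.get(l, np.zeros((n, 2 * l + 1)))
            up.append(halves[l] @ Cl[:, l + m])
            um.append(halves[l] @ Cl[:, l - m])
        out.append((np.concatenate(up), np.concatenate(um)))
    return out


def bond_invariant_vector(c_by_shell: dict, S_blocks: dict,
                          center=None, spin="total") -> InvariantVector:
    """Axially invariant vector of frame-intrinsic bond-fit coefficients."""
    blocks = _combined_blocks(c_by_shell, S_blocks)
    vals = []
    for m, (up, um) in enumerate(blocks):
        if m == 0:
            vals.append(_vech(np.outer(up, up)))
        else:
            sym = np.outer(up, up) + np.outer(um, um)
            anti = np.outer(um, up) - np.outer(up, um)
            vals.append(_vech(sym) / np.sqrt(2.0))
            vals.append(_vech(anti, anti=True) / np.sqrt(2.0))
    specs_counts = {l: S.shape[0] for l, S in S_blocks.items()}
    layout = _bond_layout_from_counts(specs_counts)
    return InvariantVector(np.concatenate(vals), layout, center, spin)


def _bond_layout_from_counts(counts: dict) -> InvariantLayout:
    lmax = max(counts)
    slots = []
    for m in range(lmax + 1):
        na = sum(n for l, n in counts.items() if l >= m)
        slots.extend(("m", m, i, j, "sym")
                     for i in range(na) for j in range(i, na))
        if m > 0:
            slots.extend(("m", m, i, j, "anti")
                         for i in range(na) for j in range(i + 1, na))
    return InvariantLayout("bond", tuple(slots))


def so2_overlap_oracle(cA_by_shell: dict, cB_by_shell: dict, S_blocks: dict,
                       n_phi: int = 64) -> float:
    """Brute-force (2pi)^-1 int_0^2pi |<rho_AB | Rz(phi) rho_CD>|^2 dphi."""
    CA = {l: np.atleast_2d(np.asarray(v, dtype=float))
          for l, v in cA_by_shell.items()}
    CB = {l: np.atleast_2d(np.asarray(v, dtype=float))
          for l, v in cB_by_shell.items()}
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    total = 0.0
    for phi in phis:
        ov = 0.0
        for l, S in S_blocks.items():
            A = CA.get(l)
            B = CB.get(l)
            if A is None or B is None:
                continue
            Brot = np.vstack([zrot_coeffs(row, l, phi) for row in B])
            ov += float(np.einsum("nm,nk,km->", A, S, Brot))
        total += ov * ov
    return total / n_phi


def simplified_bond_vector(c_by_shell: dict, S_blocks: dict,
                           mode: str = "m0_only", center=None,
                           spin="total") -> InvariantVector:
    """Reduced bond vectors: keep only m = 0 content, or a single orbital.

    ``m0_only`` restricts the full construction to the m = 0 block (what one
    obtains when fitting with m = 0 functions only, dropping the axial
    integration).  ``single_s`` / ``single_p`` assume the bond basis was
    truncated to one s (or one p) shell before fitting and yield a length-1
    vector (the squared m = 0 coefficient).
    """
    if mode not in ("m0_only", "single_s", "single_p"):
        raise ValueError(f"unknown simplified-bond mode {mode!r}")
    if mode == "m0_only":
        blocks = _combined_blocks(c_by_shell, S_blocks)
        up, _ = blocks[0]
        n0 = up.size
        slots = tuple(("m", 0, i, j, "sym")
                      for i in range(n0) for j in range(i, n0))
        return InvariantVector(_vech(np.outer(up, up)),
                               InvariantLayout("bond", slots), center, spin)
    want_l = 0 if mode == "single_s" else 1
    if want_l not in c_by_shell or set(S_blocks) != {want_l} \
            or S_blocks[want_l].shape != (1, 1):
        raise ValueError(f"{mode} expects a bond basis truncated to one "
                         f"l={want_l} shell")
    C = np.atleast_2d(np.asarray(c_by_shell[want_l], dtype=float))
    c0 = float(C[0, want_l]) * float(np.sqrt(S_blocks[want_l][0, 0]))
    slots = (("m", 0, 0, 0, "sym"),)
    return InvariantVector(np.array([c0 * c0]),
                           InvariantLayout("bond", slots), center, spin)


def truncate_bond_entry(specs, mode: str):
    """Bond-basis truncation for the single-orbital simplified variants."""
    if mode == "single_s":
        keep = [sp for sp in specs if sp.l == 0][:1]
    elif mode == "single_p":
        keep = [sp for sp in specs if sp.l == 1][:1]
    elif mode == "m0_only":
        keep = list(specs)
    else:
        raise ValueError(f"unknown simplified-bond mode {mode!r}")
    if not keep:
        raise ValueError(f"bond basis has no shell for mode {mode!r}")
    return keep
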