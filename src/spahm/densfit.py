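"""Density fitting of atomic and bond densities onto auxiliary bases.

Atomic densities are decomposed onto atom-centered auxiliary functions on
every atom of the molecule (so that centers J != I pick up the bonding
tails); bond densities onto a basis placed at the bond midpoint, expressed in
a canonical bond-local frame.

The fit minimizes the Coulomb-metric self-repulsion of the error, the
standard choice with JKFIT-type bases: solve J2c c = b, b_a = sum_mn D_mn
(a|mn).  An overlap-metric option is exposed for comparison.  Near-singular
metrics are handled by an eigenvalue pseudo-inverse with relative cutoff
1e-9 (fitting bases on close centers are near-linearly dependent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals as ints
from .chemio import AOIndexMap, BasisSet, Molecule, place_aux_shells
from .harmonics import real_wigner

METRIC_EIG_CUTOFF = 1e-9


@dataclass(frozen=True)
class AuxPlacement:
    """Auxiliary functions at arbitrary centers, with their index map.

    ``keys`` labels each center (element Z for atom-centered placements, the
    string "bond" for midpoint placements) for downstream bagging.
    """

    positions: tuple          # center index -> 3-vector (Bohr)
    specs: tuple              # center index -> tuple[ShellSpec]
    keys: tuple               # center index -> element Z or "bond"
    aux_map: AOIndexMap

    @classmethod
    def on_atoms(cls, mol: Molecule, aux_basis: BasisSet) -> "AuxPlacement":
        positions = tuple(np.array(c) for c in mol.coords)
        specs = tuple(tuple(aux_basis.for_element(z)) for z in mol.elements)
        _, aux_map = place_aux_shells(list(zip(positions, specs)))
        return cls(positions, specs, tuple(mol.elements), aux_map)

    @classmethod
    def at_point(cls, position, shell_specs, key="bond") -> "AuxPlacement":
        positions = (np.asarray(position, dtype=float),)
        specs = (tuple(shell_specs),)
        _, aux_map = place_aux_shells(list(zip(positions, specs)))
        return cls(positions, specs, (key,), aux_map)

    @property
    def placement_arg(self):
        """The (position, specs) list accepted by compute_integrals."""
        return list(zip(self.positions, self.specs))

    @property
    def n_aux(self) -> int:
        return self.aux_map.n_ao

    def center_slices(self):
        out = {}
        for i, (ic, *_r) in enumerate(self.aux_map.entries):
            out.setdefault(ic, []).append(i)
        return {ic: np.asarray(ix) for ic, ix in out.items()}


@dataclass(frozen=True)
class FitResult:
    """Solution of one density fit."""

    coeffs: np.ndarray
    metric: np.ndarray
    rhs: np.ndarray
    residual_norm: float      # Coulomb-metric fit-error deficit (see fit_density)


def _pinv_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(0.5 * (A + A.T))
    wmax = np.abs(w).max() if w.size else 1.0
    keep = w > METRIC_EIG_CUTOFF * wmax
    Ub = U[:, keep].T @ b
    return U[:, keep] @ (Ub / w[keep])


def fit_density(D_part: np.ndarray, aux: AuxPlacement, integrals,
                self_repulsion: float | None = None) -> FitResult:
    """Fit one density-matrix component onto the auxiliary placement.

    ``integrals`` must carry J2c/J3c computed for this placement.  The
    reported ``residual_norm`` is c.J2c.c - 2 c.b plus the exact density
    self-repulsion when available (then it is the true Coulomb-metric error
    norm, >= 0 up to cutoff effects); without it, the (negative) deficit of
    the first two terms is reported.
    """
    J2c, J3c = integrals.J2c, integrals.J3c
    if J3c.shape[1:] != D_part.shape or J2c.shape[0] != aux.n_aux:
        raise ValueError("integral/aux/density shape mismatch")
    b = np.einsum("amn,mn->a", J3c, D_part)
    c = _pinv_solve(J2c, b)
    res = float(c @ J2c @ c - 2.0 * c @ b)
    if self_repulsion is not None:
        res += float(self_repulsion)
    return FitResult(coeffs=c, metric=J2c, rhs=b, residual_norm=res)


def split_by_center(fit: FitResult, aux: AuxPlacement) -> dict:
    """Disjoint partition of the coefficient vector by auxiliary center."""
    return {ic: fit.coeffs[ix] for ic, ix in aux.center_slices().items()}


def coeffs_by_shell(coeffs: np.ndarray, aux: AuxPlacement, center: int) -> dict:
    """Per-center coefficients regrouped as {l: array (n_shells_l, 2l+1)}."""
    sl = aux.center_slices()[center]
    entries = [aux.aux_map.entries[i] for i in sl]
    out = {}
    by_shell = {}
    for c, (_ic, ish, l, m) in zip(coeffs[sl] if len(coeffs) == aux.n_aux
                                   else coeffs, entries):
        by_shell.setdefault((ish, l), {})[m] = c
    for (ish, l), ms in sorted(by_shell.items()):
        out.setdefault(l, []).append([ms[m] for m in range(-l, l + 1)])
    return {l: np.asarray(v) for l, v in out.items()}


# ----------------------------------------------------------------- bonds

@dataclass(frozen=True)
class BondFrame:
    """Canonical local frame of a bond: origin at the midpoint, z along it."""

    origin: np.ndarray
    z_axis: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    atoms: tuple              # canonically ordered (I, J)

    @property
    def rotation(self) -> np.ndarray:
        """Rows (x,y,z): maps lab displacements to local coordinates."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])


def build_bond_frame(mol: Molecule, I: int, J: int) -> BondFrame:
    """Midpoint-origin frame with z along the bond.

    The pair is ordered canonically (higher Z first, ties by lower atom
    index) so both argument orders give the identical frame; x is obtained
    by Gram-Schmidt of the Cartesian axis least aligned with z.
    """
    if I == J:
        raise ValueError("a bond needs two distinct atoms")
    pair = sorted([I, J], key=lambda a: (-mol.elements[a], a))
    Ri, Rj = mol.coords[pair[0]], mol.coords[pair[1]]
    d = Rj - Ri
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise ValueError(f"atoms {I} and {J} are coincident")
    z = d / nrm
    seed = np.zeros(3)
    seed[np.argmin(np.abs(z))] = 1.0
    x = seed - (seed @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return BondFrame(origin=0.5 * (Ri + Rj), z_axis=z, x_axis=x, y_axis=y,
                     atoms=tuple(pair))


def rotate_to_frame(coeffs: np.ndarray, aux: AuxPlacement,
                    U: np.ndarray) -> np.ndarray:
    """Re-express fit coefficients in a rotated frame (rows of U = new axes).

    Per shell of angular momentum l the (2l+1) coefficients transform with
    the real-harmonic rotation matrix W(U).
    """
    out = np.empty_like(coeffs)
    entries = aux.aux_map.entries
    i = 0
    while i < len(entries):
        l = entries[i][2]
        W = real_wigner(l, U)
        out[i:i + 2 * l + 1] = W @ coeffs[i:i + 2 * l + 1]
        i += 2 * l + 1
    return out


def fit_bond_density(D_IJ: np.ndarray, frame: BondFrame, bond_entry,
                     mol: Molecule, orbital_basis: BasisSet,
                     integrals_factory=None) -> tuple:
    """Fit a bond density on midpoint-centered functions, frame-intrinsic.

    Returns (FitResult with lab-frame data, local-frame coefficient vector,
    AuxPlacement).  ``integrals_factory(mol, basis, placement)`` defaults to
    :func:`spahm.chemio.compute_integrals` and exists for test injection.
    """
    from .chemio import compute_integrals
    factory = integrals_factory or compute_integrals
    aux = AuxPlacement.at_point(frame.origin, bond_entry)
    bundle = factory(mol, orbital_basis, aux.placement_arg)
    fit = fit_density(D_IJ, aux, bundle)
    c_local = rotate_to_frame(fit.coeffs, aux, frame.rotation)
    return fit, c_local, aux
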