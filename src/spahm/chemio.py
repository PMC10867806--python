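"""Molecular data model, basis registry and integral contracts.

Internal length unit is Bohr; XYZ files are read in Angstrom and converted.
All basis functions are pure real-spherical-harmonic Gaussians with the
m = -l..+l ordering recorded in :class:`AOIndexMap` (single source of truth
for every downstream module).
"""

from __future__ import annotations

import importlib.resources as _res
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import integrals as ints
from .integrals import PlacedShell

ANGSTROM_PER_BOHR = 0.52917721092

_SYMBOLS = ["X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
            "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar"]
_Z = {s.lower(): z for z, s in enumerate(_SYMBOLS)}

_REGISTRY = {
    "minao": "minao_synthetic.basis",
    "cc-pvdz/jkfit": "ccpvdz_jkfit_synthetic.basis",
    "bond-default": "bond_default.basis",
}

_LNAMES = "SPDFGHI"


def element_symbol(z: int) -> str:
    return _SYMBOLS[z]


def element_number(symbol: str) -> int:
    try:
        return _Z[symbol.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


# ------------------------------------------------------------------ types

@dataclass(frozen=True)
class Molecule:
    """Nuclear charges, positions (Bohr), total charge and spin multiplicity."""

    elements: tuple
    coords: np.ndarray
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        elements = tuple(int(z) for z in self.elements)
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(elements) != len(coords):
            raise ValueError("elements and coords length mismatch")
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "coords", coords)
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer (2S+1)")
        ne = self.n_electrons
        if ne < 0:
            raise ValueError(f"negative electron count ({ne})")
        if (ne + self.multiplicity - 1) % 2 != 0:
            raise ValueError(
                f"impossible charge/multiplicity: {ne} electrons cannot have "
                f"multiplicity {self.multiplicity}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        return int(sum(self.elements)) - self.charge

    def translated(self, shift) -> "Molecule":
        return Molecule(self.elements, self.coords + np.asarray(shift),
                        self.charge, self.multiplicity)

    def rotated(self, R) -> "Molecule":
        return Molecule(self.elements, self.coords @ np.asarray(R).T,
                        self.charge, self.multiplicity)

    def permuted(self, order) -> "Molecule":
        order = list(order)
        return Molecule([self.elements[i] for i in order], self.coords[order],
                        self.charge, self.multiplicity)


@dataclass(frozen=True)
class ShellSpec:
    """One contracted shell: angular momentum, exponents (Bohr^-2), contraction."""

    l: int
    exponents: np.ndarray
    contraction: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.exponents, dtype=float)
        c = np.asarray(self.contraction, dtype=float)
        if self.l < 0:
            raise ValueError("negative angular momentum")
        if e.size == 0 or np.any(e <= 0):
            raise ValueError("shell needs positive exponents")
        if c.shape != e.shape:
            raise ValueError("contraction length must match exponents")
        object.__setattr__(self, "exponents", e)
        object.__setattr__(self, "contraction", c)

    def placed(self, center) -> PlacedShell:
        return PlacedShell(self.l, self.exponents, self.contraction, center)


@dataclass(frozen=True)
class BasisSet:
    """Per-element shell lists."""

    name: str
    shells: dict  # Z -> list[ShellSpec]

    def for_element(self, z: int):
        if z not in self.shells:
            raise KeyError(
                f"basis {self.name!r} has no entry for element "
                f"{element_symbol(z) if z < len(_SYMBOLS) else z}")
        return self.shells[z]

    def covers(self, molecule: Molecule) -> bool:
        return all(z in self.shells for z in molecule.elements)


@dataclass(frozen=True)
class AOIndexMap:
    """(center index, shell index, l, m) per AO; m runs -l..+l within a shell."""

    entries: tuple  # of (center, shell, l, m)
    convention: str = "real spherical harmonics, m = -l..+l"

    @classmethod
    def build(cls, shell_centers, shell_ls) -> "AOIndexMap":
        ent = []
        for ish, (ic, l) in enumerate(zip(shell_centers, shell_ls)):
            for m in range(-l, l + 1):
                ent.append((ic, ish, l, m))
        return cls(tuple(ent))

    @property
    def n_ao(self) -> int:
        return len(self.entries)

    def ao_indices_of_center(self, ic: int) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.entries) if e[0] == ic],
                        dtype=int)


@dataclass
class IntegralBundle:
    """Overlap, core-Hamiltonian and density-fitting integrals for one system."""

    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    J2c: np.ndarray
    J3c: np.ndarray                    # (naux, nao, nao)
    ao_map: AOIndexMap
    aux_map: AOIndexMap
    orbital_shells: list = field(default_factory=list)
    aux_shells: list = field(default_factory=list)


# ------------------------------------------------------------------- I/O

def read_xyz(path, charge: int | None = None,
             multiplicity: int | None = None) -> Molecule:
    """Read a standard XYZ file (Angstrom).

    Charge/multiplicity may be given as arguments or parsed from the comment
    line (``charge=c multiplicity=m``, also accepting ``mult=``); arguments
    win.  Missing values default to 0 / 1.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1 is not an atom count") from None
    if len(lines) < n + 2:
        raise ValueError(f"{path}: expected {n} atom lines, file too short")
    comment = lines[1] if len(lines) > 1 else ""
    parsed = {}
    for tok in comment.replace(",", " ").split():
        for key in ("charge", "multiplicity", "mult"):
            if tok.lower().startswith(key + "="):
                try:
                    parsed["multiplicity" if key != "charge" else "charge"] = \
                        int(tok.split("=", 1)[1])
                except ValueError:
                    pass
    if charge is None:
        charge = parsed.get("charge", 0)
    if multiplicity is None:
        multiplicity = parsed.get("multiplicity", 1)
    elements, coords = [], []
    for iln in range(2, 2 + n):
        parts = lines[iln].split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ at line {iln + 1}")
        elements.append(element_number(parts[0]))
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise ValueError(f"{path}: malformed coordinates at line {iln + 1}") \
                from None
    return Molecule(elements, np.asarray(coords) / ANGSTROM_PER_BOHR,
                    charge, multiplicity)


def _parse_basis_text(text: str):
    """Parse the bundled basis dialect.

    Blocks start with ``element <symbol>`` (atom-centered sets) or
    ``pair <X-Y>|default`` (bond sets); inside a block, a line with a single
    angular-momentum letter (S/P/D/F/G) opens a contraction, followed by
    ``exponent coefficient`` rows.  ``#`` starts a comment.
    """
    by_element, by_pair = {}, {}
    current = None
    cur_l, cur_rows = None, []

    def flush_shell():
        nonlocal cur_l, cur_rows
        if cur_l is not None:
            rows = np.asarray(cur_rows, dtype=float)
            current.append(ShellSpec(cur_l, rows[:, 0], rows[:, 1]))
        cur_l, cur_rows = None, []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0].lower() in ("element", "pair"):
            flush_shell()
            current = []
            if tok[0].lower() == "element":
                by_element[element_number(tok[1])] = current
            else:
                by_pair[tok[1].lower()] = current
        elif len(tok) == 1 and tok[0].upper() in _LNAMES:
            flush_shell()
            cur_l = _LNAMES.index(tok[0].upper())
        else:
            cur_rows.append([float(tok[0]), float(tok[1])])
    flush_shell()
    return by_element, by_pair


def _read_basis_source(source: str) -> str:
    key = str(source).lower()
    if key in _REGISTRY:
        return (_res.files("spahm.data") / _REGISTRY[key]).read_text()
    return Path(source).read_text()


def load_basis(source, elements) -> BasisSet:
    """Load an atom-centered basis from a registry name or a file path."""
    by_element, _ = _parse_basis_text(_read_basis_source(source))
    missing = sorted(set(elements) - set(by_element))
    if missing:
        raise KeyError(
            f"basis {source!r} missing elements: "
            + ", ".join(element_symbol(z) if z < len(_SYMBOLS) else str(z)
                        for z in missing))
    name = str(source)
    return BasisSet(name, {z: by_element[z] for z in set(elements)})


def load_bond_basis(source="bond-default") -> dict:
    """Bond-centered fitting basis keyed by sorted element pair "X-Y".

    Key ``default`` is the fallback for pairs without an explicit entry.
    """
    _, by_pair = _parse_basis_text(_read_basis_source(source))
    if not by_pair:
        raise ValueError(f"{source!r} contains no 'pair' blocks")
    return by_pair


def bond_basis_entry(bond_basis: dict, z_i: int, z_j: int):
    key = "-".join(sorted([element_symbol(z_i), element_symbol(z_j)])).lower()
    if key in bond_basis:
        return bond_basis[key]
    if "default" in bond_basis:
        return bond_basis["default"]
    raise KeyError(f"no bond basis for pair {key!r} and no default entry")


# -------------------------------------------------------------- integrals

def place_orbital_shells(mol: Molecule, basis: BasisSet):
    shells, centers, ls = [], [], []
    for ia, z in enumerate(mol.elements):
        for spec in basis.for_element(z):
            shells.append(spec.placed(mol.coords[ia]))
            centers.append(ia)
            ls.append(spec.l)
    return shells, AOIndexMap.build(centers, ls)


def place_aux_shells(aux_placement):
    """aux_placement: list of (position Bohr, list[ShellSpec])."""
    shells, centers, ls = [], [], []
    for ic, (pos, specs) in enumerate(aux_placement):
        for spec in specs:
            shells.append(spec.placed(np.asarray(pos, dtype=float)))
            centers.append(ic)
            ls.append(spec.l)
    return shells, AOIndexMap.build(centers, ls)


def _pairwise(op, shells_a, shells_b=None):
    symmetric = shells_b is None
    if symmetric:
        shells_b = shells_a
    na, nb = ints.n_ao(shells_a), ints.n_ao(shells_b)
    out = np.zeros((na, nb))
    oa = np.cumsum([0] + [s.nfun for s in shells_a])
    ob = np.cumsum([0] + [s.nfun for s in shells_b])
    for i, sa in enumerate(shells_a):
        for j, sb in enumerate(shells_b):
            if symmetric and j < i:
                continue
            blk = op(sa, sb)
            out[oa[i]:oa[i + 1], ob[j]:ob[j + 1]] = blk
            if symmetric and j > i:
                out[ob[j]:ob[j + 1], oa[i]:oa[i + 1]] = blk.T
    return out


def compute_integrals(mol: Molecule, orbital_basis: BasisSet,
                      aux_placement=()) -> IntegralBundle:
    """Overlap/kinetic/nuclear matrices plus 2c/3c Coulomb fitting integrals.

    ``aux_placement`` is a list of (center position in Bohr, list of
    ShellSpec); positions may be atoms or arbitrary points (bond midpoints).
    Linear dependence in the auxiliary metric is left to the fitting step.
    """
    shells, ao_map = place_orbital_shells(mol, orbital_basis)
    S = _pairwise(ints.overlap, shells)
    T = _pairwise(ints.kinetic, shells)
    V = _pairwise(
        lambda a, b: ints.nuclear_attraction(a, b, mol.elements, mol.coords),
        shells)
    aux_shells, aux_map = place_aux_shells(aux_placement)
    nao = ao_map.n_ao
    if aux_shells:
        J2c = _pairwise(ints.eri2c, aux_shells)
        J3c = np.zeros((aux_map.n_ao, nao, nao))
        off_a = np.cumsum([0] + [s.nfun for s in aux_shells])
        off_o = np.cumsum([0] + [s.nfun for s in shells])
        for m, sm in enumerate(shells):
            for n, sn in enumerate(shells):
                if n < m:
                    continue
                blocks = ints.eri3c_row(aux_shells, sm, sn)
                for i, blk in enumerate(blocks):
                    J3c[off_a[i]:off_a[i + 1], off_o[m]:off_o[m + 1],
                        off_o[n]:off_o[n + 1]] = blk
                    if n > m:
                        J3c[off_a[i]:off_a[i + 1], off_o[n]:off_o[n + 1],
                            off_o[m]:off_o[m + 1]] = \
                            np.transpose(blk, (0, 2, 1))
    else:
        J2c = np.zeros((0, 0))
        J3c = np.zeros((0, nao, nao))
    return IntegralBundle(S=S, T=T, V=V, J2c=J2c, J3c=J3c, ao_map=ao_map,
                          aux_map=aux_map, orbital_shells=shells,
                          aux_shells=aux_shells)


def evaluate_ao_on_grid(mol: Molecule, basis: BasisSet,
                        points) -> np.ndarray:
    """chi_mu(r) on Cartesian points (Bohr), (npoints, nao); AOIndexMap order."""
    shells, _ = place_orbital_shells(mol, basis)
    return ints.eval_on_grid(shells, points)
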