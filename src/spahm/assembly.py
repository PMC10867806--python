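"""Bagging of per-center invariant vectors into fixed-length atomic features.

SPAHM(a): for each atom I, the invariant vectors of the fit of rho_I on every
center J are grouped by the element of J ("bags"), summed within each bag,
and concatenated in ascending atomic number; elements absent from a molecule
contribute zero blocks, so one dataset-wide layout serves all molecules.

SPAHM(b): for each atom, the bond vectors towards every partner atom are
grouped by the partner's element and summed; bags are indexed by partner
element only (the central element is implicit because regression models are
trained per element).

Open shells: the alpha- and beta-channel vectors are concatenated, which is
what makes a radical cation distinguishable from its neutral parent at the
same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import densfit, invariants, partition
from .chemio import BasisSet, Molecule, compute_integrals, element_symbol
from .densfit import AuxPlacement, build_bond_frame, fit_density, \
    rotate_to_frame, split_by_center
from .guess import GuessSpec, guess_density
from .harmonics import real_wigner
from .invariants import atomic_invariant_vector, atomic_layout, \
    bond_invariant_vector, bond_layout, radial_overlap_blocks

__all__ = ["BagLayout", "AtomRep", "bag_atomic", "bag_bond", "concat_spin",
           "dataset_layout", "spahm_a", "spahm_b", "represent_dataset"]


@dataclass(frozen=True)
class BagLayout:
    """Dataset-wide bag structure of the final per-atom vectors."""

    mode: str                 # "a" | "b"
    elements: tuple           # ascending atomic numbers
    bag_lengths: dict         # element Z -> invariant-vector length
    spin_mode: str = "total"  # "total" | "alpha_beta"

    def __post_init__(self):
        if self.mode not in ("a", "b"):
            raise ValueError("mode must be 'a' or 'b'")
        if self.spin_mode not in ("total", "alpha_beta"):
            raise ValueError("spin_mode must be 'total' or 'alpha_beta'")
        object.__setattr__(self, "elements", tuple(sorted(self.elements)))

    @property
    def channel_length(self) -> int:
        return int(sum(self.bag_lengths[z] for z in self.elements))

    @property
    def total_length(self) -> int:
        return self.channel_length * (2 if self.spin_mode == "alpha_beta" else 1)

    def offset(self, z: int) -> int:
        if z not in self.bag_lengths:
            raise KeyError(f"element {element_symbol(z)} not in layout "
                           f"{[element_symbol(e) for e in self.elements]}")
        off = 0
        for e in self.elements:
            if e == z:
                return off
            off += self.bag_lengths[e]
        raise KeyError(z)


@dataclass(frozen=True)
class AtomRep:
    """Final bagged representation of one atom."""

    values: np.ndarray
    element: int
    molecule_id: object
    atom_index: int
    layout: BagLayout
    spin: str = "total"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        expect = self.layout.channel_length * \
            (2 if self.spin == "alpha_beta" else 1)
        if v.shape != (expect,):
            raise ValueError(f"representation length {v.shape} does not "
                             f"match layout ({expect})")
        object.__setattr__(self, "values", v)


def _bag(vectors, layout: BagLayout, element: int, molecule_id, atom_index,
         spin) -> AtomRep:
    out = np.zeros(layout.channel_length)
    for z, vec in vectors:
        off = layout.offset(z)
        n = layout.bag_lengths[z]
        if vec.values.shape != (n,):
            raise ValueError(
                f"invariant vector for element {element_symbol(z)} has "
                f"length {vec.values.size}, layout expects {n}")
        out[off:off + n] += vec.values
    return AtomRep(out, element, molecule_id, atom_index, layout, spin)


def bag_atomic(v_map, layout: BagLayout, element: int, molecule_id=None,
               atom_index=0, spin="total") -> AtomRep:
    """Sum SPAHM(a) per-center vectors into element bags.

    ``v_map``: iterable of (element Z of center J, InvariantVector of the
    coefficients on J).
    """
    return _bag(v_map, layout, element, molecule_id, atom_index, spin)


def bag_bond(v_bonds, layout: BagLayout, element: int, molecule_id=None,
             atom_index=0, spin="total") -> AtomRep:
    """Sum SPAHM(b) bond vectors into partner-element bags.

    ``v_bonds``: iterable of (partner element Z, InvariantVector of the
    bond).  An atom with no partners yields the all-zero vector (valid).
    """
    return _bag(v_bonds, layout, element, molecule_id, atom_index, spin)


def concat_spin(rep_alpha: AtomRep, rep_beta: AtomRep) -> AtomRep:
    if rep_alpha.layout != rep_beta.layout or \
            rep_alpha.atom_index != rep_beta.atom_index:
        raise ValueError("spin channels have mismatching layout or atom")
    return AtomRep(np.concatenate([rep_alpha.values, rep_beta.values]),
                   rep_alpha.element, rep_alpha.molecule_id,
                   rep_alpha.atom_index, rep_alpha.layout, "alpha_beta")


# ---------------------------------------------------------------- layouts

def dataset_layout(molecules=None, aux_basis: BasisSet | None = None,
                   mode: str = "a", spin_mode: str = "total",
                   bond_basis: dict | None = None,
                   elements=None) -> BagLayout:
    """Deterministic dataset-wide BagLayout.

    The element set is the union over ``molecules`` (or an explicit
    ``elements`` set).  Mode "a" takes per-element invariant lengths from the
    atom-centered auxiliary basis; mode "b" takes per-partner-element bond
    vector lengths from the bond basis (keyed by element pair, with the
    ``default`` fallback).
    """
    if elements is None:
        if not molecules:
            raise ValueError("need molecules or an explicit element set")
        elements = sorted({z for m in molecules for z in m.elements})
    elements = sorted(int(z) for z in elements)
    lengths = {}
    for z in elements:
        if mode == "a":
            if aux_basis is None:
                raise ValueError("mode 'a' needs the auxiliary basis")
            lengths[z] = atomic_layout(aux_basis.for_element(z)).length
        else:
            if bond_basis is None:
                raise ValueError("mode 'b' needs the bond basis")
            # partner-element bag length; with per-pair bases all pairs that
            # share the partner element must agree, which holds for the
            # bundled single-entry basis and is checked at bagging time.
            from .chemio import bond_basis_entry
            entry = bond_basis_entry(bond_basis, z, z)
            lengths[z] = bond_layout(entry).length
    return BagLayout(mode, tuple(elements), lengths, spin_mode)


# --------------------------------------------------------------- pipelines

def _spin_channels(mol: Molecule, spin_mode: str):
    if spin_mode == "alpha_beta":
        return ["alpha", "beta"]
    return ["total"]


def resolve_spin_mode(molecules, spin_mode: str = "auto") -> str:
    """'auto': alpha_beta as soon as any molecule in the set is open shell
    (mixed sets need one common vector length), else total."""
    if spin_mode in ("total", "alpha_beta"):
        return spin_mode
    if spin_mode != "auto":
        raise ValueError(f"unknown spin mode {spin_mode!r}")
    return "alpha_beta" if any(m.multiplicity != 1 for m in molecules) \
        else "total"


def spahm_a(mol: Molecule, orbital_basis: BasisSet, aux_basis: BasisSet,
            layout: BagLayout | None = None,
            guess_spec: GuessSpec | None = None,
            molecule_id=None) -> list:
    """SPAHM(a) representations for every atom of one molecule."""
    if layout is None:
        layout = dataset_layout([mol], aux_basis, "a",
                                resolve_spin_mode([mol]))
    aux = AuxPlacement.on_atoms(mol, aux_basis)
    bundle = compute_integrals(mol, orbital_basis, aux.placement_arg)
    sd = guess_density(mol, orbital_basis, bundle, guess_spec)
    s_blocks = {z: radial_overlap_blocks(aux_basis.for_element(z))
                for z in set(mol.elements)}
    chan_reps = {}
    for spin in _spin_channels(mol, layout.spin_mode):
        part = partition.partition_density(
            sd.channel(spin), bundle.S, bundle.ao_map, mol.n_atoms, spin)
        reps = []
        for I in range(mol.n_atoms):
            fit = fit_density(part.atom_blocks[I], aux, bundle)
            vecs = []
            for J in split_by_center(fit, aux):
                zJ = mol.elements[J]
                c_shell = densfit.coeffs_by_shell(fit.coeffs, aux, J)
                vecs.append((zJ, atomic_invariant_vector(
                    c_shell, s_blocks[zJ], center=J, spin=spin)))
            reps.append(bag_atomic(vecs, layout, mol.elements[I],
                                   molecule_id, I, spin))
        chan_reps[spin] = reps
    if layout.spin_mode == "alpha_beta":
        return [concat_spin(a, b) for a, b in
                zip(chan_reps["alpha"], chan_reps["beta"])]
    return chan_reps["total"]


_FLIP = np.diag([1.0, -1.0, -1.0])   # z -> -z keeping a right-handed frame


def _bond_vector(mol, orbital_basis, D_IJ, I, J, bond_entry, s_blocks,
                 spin, j2c_cache, bundle):
    """Frame-intrinsic, direction-averaged invariant vector of one bond."""
    frame = build_bond_frame(mol, I, J)
    aux = AuxPlacement.at_point(frame.origin, bond_entry)
    from .chemio import place_aux_shells
    from . import integrals as ints
    aux_shells, _ = place_aux_shells(aux.placement_arg)
    key = id(bond_entry)
    if key not in j2c_cache:
        from .chemio import _pairwise
        j2c_cache[key] = _pairwise(ints.eri2c, aux_shells)
    naux = aux.n_aux
    nao = bundle.ao_map.n_ao
    J3c = np.zeros((naux, nao, nao))
    off_a = np.cumsum([0] + [s.nfun for s in aux_shells])
    shells = bundle.orbital_shells
    off_o = np.cumsum([0] + [s.nfun for s in shells])
    for m, sm in enumerate(shells):
        for n, sn in enumerate(shells):
            if n < m:
                continue
            for i, blk in enumerate(ints.eri3c_row(aux_shells, sm, sn)):
                J3c[off_a[i]:off_a[i + 1], off_o[m]:off_o[m + 1],
                    off_o[n]:off_o[n + 1]] = blk
                if n > m:
                    J3c[off_a[i]:off_a[i + 1], off_o[n]:off_o[n + 1],
                        off_o[m]:off_o[m + 1]] = np.transpose(blk, (0, 2, 1))

    from types import SimpleNamespace
    carrier = SimpleNamespace(J2c=j2c_cache[key], J3c=J3c)
    fit = fit_density(D_IJ, aux, carrier)
    c_local = rotate_to_frame(fit.coeffs, aux, frame.rotation)
    c_flip = rotate_to_frame(c_local, aux, _FLIP)
    v_loc = bond_invariant_vector(densfit.coeffs_by_shell(c_local, aux, 0),
                                  s_blocks, center=(I, J), spin=spin)
    v_flip = bond_invariant_vector(densfit.coeffs_by_shell(c_flip, aux, 0),
                                   s_blocks, center=(I, J), spin=spin)
    return invariants.InvariantVector(0.5 * (v_loc.values + v_flip.values),
                                      v_loc.layout, (I, J), spin)


def spahm_b(mol: Molecule, orbital_basis: BasisSet, bond_basis: dict,
            layout: BagLayout | None = None,
            guess_spec: GuessSpec | None = None,
            molecule_id=None, bond_cutoff: float | None = None) -> list:
    """SPAHM(b) representations for every atom of one molecule.

    ``bond_cutoff`` (Bohr) optionally skips distant atom pairs.
    """
    from .chemio import bond_basis_entry
    if layout is None:
        layout = dataset_layout([mol], mode="b", bond_basis=bond_basis,
                                spin_mode=resolve_spin_mode([mol]))
    bundle = compute_integrals(mol, orbital_basis, ())
    sd = guess_density(mol, orbital_basis, bundle, guess_spec)
    entry_blocks = {}
    j2c_cache = {}
    chan_reps = {}
    for spin in _spin_channels(mol, layout.spin_mode):
        part = partition.partition_density(
            sd.channel(spin), bundle.S, bundle.ao_map, mol.n_atoms, spin,
            bond_cutoff=bond_cutoff, coords=mol.coords)
        per_atom = {I: [] for I in range(mol.n_atoms)}
        for (I, J), D_IJ in part.bond_blocks.items():
            entry = bond_basis_entry(
                bond_basis, mol.elements[I], mol.elements[J])
            if id(entry) not in entry_blocks:
                entry_blocks[id(entry)] = radial_overlap_blocks(entry)
            v = _bond_vector(mol, orbital_basis, D_IJ, I, J, entry,
                             entry_blocks[id(entry)], spin, j2c_cache, bundle)
            per_atom[I].append((mol.elements[J], v))
            per_atom[J].append((mol.elements[I], v))
        reps = [bag_bond(per_atom[I], layout, mol.elements[I],
                         molecule_id, I, spin)
                for I in range(mol.n_atoms)]
        chan_reps[spin] = reps
    if layout.spin_mode == "alpha_beta":
        return [concat_spin(a, b) for a, b in
                zip(chan_reps["alpha"], chan_reps["beta"])]
    return chan_reps["total"]


def represent_dataset(molecules, orbital_basis: BasisSet, mode: str = "a",
                      aux_basis: BasisSet | None = None,
                      bond_basis: dict | None = None,
                      spin_mode: str = "auto",
                      guess_spec: GuessSpec | None = None,
                      bond_cutoff: float | None = None):
    """Representations for a whole dataset under one shared layout.

    Returns (list over molecules of lists of AtomRep, BagLayout).
    """
    spin = resolve_spin_mode(molecules, spin_mode)
    layout = dataset_layout(molecules, aux_basis, mode, spin, bond_basis)
    out = []
    for i, mol in enumerate(molecules):
        if mode == "a":
            out.append(spahm_a(mol, orbital_basis, aux_basis, layout,
                               guess_spec, molecule_id=i))
        else:
            out.append(spahm_b(mol, orbital_basis, bond_basis, layout,
                               guess_spec, molecule_id=i,
                               bond_cutoff=bond_cutoff))
    return out, layout
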