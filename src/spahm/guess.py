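"""Non-iterative guess Hamiltonians and the spin-resolved guess density.

A lightweight one-electron Hamiltonian is built (core, GWH, or a one-shot
Fock over superposed atomic densities), diagonalized once against the AO
overlap, and the lowest orbitals are filled Aufbau-style to give per-spin
density matrices.  No SCF anywhere.

Open shells use one common Hamiltonian for both spins (restricted-open-style
filling): alpha and beta densities share spatial orbitals and differ only in
occupation counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from . import integrals as ints
from .chemio import BasisSet, IntegralBundle, Molecule

GUESS_KINDS = ("core", "gwh", "sad_fock", "plugin")

#: Spherically averaged neutral-atom shell occupations (electrons per shell)
#: in the minimal basis, per element, ordered as the basis lists the shells.
_SAD_OCC = {
    1: [1.0],                       # H: 1s^1
    6: [2.0, 2.0, 2.0],             # C: 1s 2s 2p^2
    7: [2.0, 2.0, 3.0],             # N
    8: [2.0, 2.0, 4.0],             # O
    16: [2.0, 2.0, 2.0, 6.0, 4.0],  # S: 1s 2s 3s 2p^6 3p^4
}


@dataclass(frozen=True)
class GuessSpec:
    """Which one-electron Hamiltonian to build.

    ``plugin`` accepts any externally constructed matrix via a callable
    ``(Molecule, BasisSet, IntegralBundle) -> ndarray`` so that potentials
    not implemented here (e.g. Laikov-Briling) can be slotted in.
    """

    kind: str = "sad_fock"
    plugin: object = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in GUESS_KINDS:
            raise ValueError(f"unknown guess kind {self.kind!r}; "
                             f"choose from {GUESS_KINDS}")
        if (self.kind == "plugin") != (self.plugin is not None):
            raise ValueError("plugin callable required iff kind == 'plugin'")


@dataclass(frozen=True)
class SpinDensity:
    """Per-spin one-particle density matrices in the AO basis."""

    D_alpha: np.ndarray
    D_beta: np.ndarray
    S: np.ndarray
    mo_energies: np.ndarray         # shared spatial orbitals (Hartree)
    n_alpha: int
    n_beta: int

    @property
    def D_total(self) -> np.ndarray:
        return self.D_alpha + self.D_beta

    def channel(self, spin: str) -> np.ndarray:
        return {"alpha": self.D_alpha, "beta": self.D_beta,
                "total": self.D_total}[spin]


def assign_occupations(n_electrons: int, multiplicity: int):
    """Split electrons into (n_alpha, n_beta) for a given 2S+1."""
    if (n_electrons + multiplicity - 1) % 2 != 0:
        raise ValueError(f"{n_electrons} electrons cannot have "
                         f"multiplicity {multiplicity}")
    n_alpha = (n_electrons + multiplicity - 1) // 2
    n_beta = (n_electrons - multiplicity + 1) // 2
    if n_beta < 0 or n_alpha < 0:
        raise ValueError(f"impossible occupation: n_alpha={n_alpha}, "
                         f"n_beta={n_beta}")
    return n_alpha, n_beta


def _sad_density(mol: Molecule, basis: BasisSet, ao_map) -> np.ndarray:
    """Diagonal spin-summed density of superposed spherically averaged atoms."""
    occs = []
    for ia, z in enumerate(mol.elements):
        specs = basis.for_element(z)
        try:
            shell_occ = _SAD_OCC[z]
        except KeyError:
            raise ValueError(f"no tabulated atomic occupations for Z={z}") \
                from None
        if len(shell_occ) != len(specs):
            raise ValueError(f"atomic occupations for Z={z} expect "
                             f"{len(shell_occ)} shells, basis has {len(specs)}")
        for spec, ne in zip(specs, shell_occ):
            occs.extend([ne / (2 * spec.l + 1)] * (2 * spec.l + 1))
    return np.diag(occs)


def build_guess_hamiltonian(mol: Molecule, basis: BasisSet, spec: GuessSpec,
                            integrals: IntegralBundle) -> np.ndarray:
    """One-electron Hamiltonian matrix (Hartree) in the orbital basis."""
    hcore = integrals.T + integrals.V
    if spec.kind == "core":
        return hcore
    if spec.kind == "gwh":
        # Diagonal elements are spherically averaged within each shell
        # (trace over m): the textbook per-m diagonal would make the
        # spectrum depend on the molecule's orientation for l > 0 shells,
        # which would leak into every downstream representation.
        K = float(spec.parameters.get("K", 1.75))
        d = np.diag(hcore).copy()
        shells = {}
        for i, (_c, ish, _l, _m) in enumerate(integrals.ao_map.entries):
            shells.setdefault(ish, []).append(i)
        for ix in shells.values():
            d[ix] = d[ix].mean()
        H = 0.5 * K * (d[:, None] + d[None, :]) * integrals.S
        np.fill_diagonal(H, d)
        return H
    if spec.kind == "sad_fock":
        D = _sad_density(mol, basis, integrals.ao_map)
        shells = integrals.orbital_shells
        nao = integrals.ao_map.n_ao
        eri = np.zeros((nao, nao, nao, nao))
        off = np.cumsum([0] + [s.nfun for s in shells])
        for i, sa in enumerate(shells):
            for j, sb in enumerate(shells):
                if j < i:
                    continue
                for k, sc in enumerate(shells):
                    for l, sd in enumerate(shells):
                        if l < k or (k, l) < (i, j):
                            continue
                        blk = ints.eri4c(sa, sb, sc, sd)
                        for (p, q, r, s), b in (
                                ((i, j, k, l), blk),
                                ((j, i, k, l), blk.transpose(1, 0, 2, 3)),
                                ((i, j, l, k), blk.transpose(0, 1, 3, 2)),
                                ((j, i, l, k), blk.transpose(1, 0, 3, 2))):
                            eri[off[p]:off[p + 1], off[q]:off[q + 1],
                                off[r]:off[r + 1], off[s]:off[s + 1]] = b
                            eri[off[r]:off[r + 1], off[s]:off[s + 1],
                                off[p]:off[p + 1], off[q]:off[q + 1]] = \
                                b.transpose(2, 3, 0, 1)
        J = np.einsum("pqrs,rs->pq", eri, D)
        Kx = np.einsum("prqs,rs->pq", eri, D)
        F = hcore + J - 0.5 * Kx
        return 0.5 * (F + F.T)
    # plugin
    H = np.asarray(spec.plugin(mol, basis, integrals), dtype=float)
    if H.shape != integrals.S.shape:
        raise ValueError("plugin Hamiltonian has wrong shape")
    return H


def solve_guess(H: np.ndarray, integrals: IntegralBundle,
                n_alpha: int, n_beta: int) -> SpinDensity:
    """Solve HC = SCe once and fill the lowest orbitals per spin channel.

    Degeneracies at the Fermi level are resolved by ascending eigenvalue then
    eigensolver column order (documented convention; representations built on
    open degenerate shells are convention-dependent).
    """
    S = integrals.S
    nao = S.shape[0]
    if max(n_alpha, n_beta) > nao:
        raise ValueError(f"cannot place {max(n_alpha, n_beta)} electrons of "
                         f"one spin in {nao} orbitals")
    e, C = sla.eigh(H, S)
    occ = [C[:, :n] @ C[:, :n].T for n in (n_alpha, n_beta)]
    return SpinDensity(D_alpha=occ[0], D_beta=occ[1], S=S, mo_energies=e,
                       n_alpha=n_alpha, n_beta=n_beta)


def guess_density(mol: Molecule, basis: BasisSet, integrals: IntegralBundle,
                  spec: GuessSpec | None = None) -> SpinDensity:
    """Convenience pipeline: Hamiltonian -> occupations -> densities."""
    spec = spec or GuessSpec()
    H = build_guess_hamiltonian(mol, basis, spec, integrals)
    na, nb = assign_occupations(mol.n_electrons, mol.multiplicity)
    return solve_guess(H, integrals, na, nb)
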