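"""Built-in small molecules and a generator of randomized variants.

Equilibrium-quality geometries (constructed from standard bond lengths and
angles) for the closed- and open-shell fixtures used throughout the tests,
plus a generator of "random small organics": template molecules with
Gaussian coordinate jitter (sigma 0.05 Angstrom by default) and, optionally,
radical-cation charge states.  The generator is the data source for the
self-contained regression experiments; it emulates geometric and charge
diversity, not conformational chemistry.
"""

from __future__ import annotations

import numpy as np

from .chemio import ANGSTROM_PER_BOHR, Molecule

__all__ = ["molecule", "available", "radical_pairs", "random_molecules"]


def _ang(coords):
    return np.asarray(coords, dtype=float) / ANGSTROM_PER_BOHR


def _h2():
    return Molecule([1, 1], _ang([[0, 0, 0], [0, 0, 0.74]]))


def _h2o(charge=0, multiplicity=1):
    # r(OH) = 0.9572 A, HOH = 104.52 deg
    r, th = 0.9572, np.deg2rad(104.52) / 2
    return Molecule([8, 1, 1], _ang([[0, 0, 0],
                                     [0, r * np.sin(th), r * np.cos(th)],
                                     [0, -r * np.sin(th), r * np.cos(th)]]),
                    charge, multiplicity)


def _nh3():
    # r(NH) = 1.012 A, HNH = 106.7 deg
    r, hnh = 1.012, np.deg2rad(106.7)
    # polar angle from C3 axis reproducing the HNH angle
    ct = np.cos(hnh)
    cos_theta = np.sqrt((1.0 + 2.0 * ct) / 3.0) if (1 + 2 * ct) > 0 else 0.0
    st = np.sqrt(1.0 - cos_theta ** 2)
    coords = [[0, 0, 0]]
    for k in range(3):
        phi = 2 * np.pi * k / 3
        coords.append([r * st * np.cos(phi), r * st * np.sin(phi),
                       r * cos_theta])
    return Molecule([7, 1, 1, 1], _ang(coords))


def _ch4():
    r = 1.089
    d = r / np.sqrt(3.0)
    coords = [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
    return Molecule([6, 1, 1, 1, 1], _ang(coords))


def _h2co():
    # r(CO) = 1.205, r(CH) = 1.111 A, HCH = 116.5 deg
    rco, rch, hch = 1.205, 1.111, np.deg2rad(116.5)
    s, c = np.sin(hch / 2), np.cos(hch / 2)
    coords = [[0, 0, 0], [0, 0, rco],
              [rch * s, 0, -rch * c], [-rch * s, 0, -rch * c]]
    return Molecule([6, 8, 1, 1], _ang(coords))


def _ch3():
    # planar methyl radical, r(CH) = 1.079 A
    r = 1.079
    coords = [[0, 0, 0]]
    for k in range(3):
        phi = 2 * np.pi * k / 3
        coords.append([r * np.cos(phi), r * np.sin(phi), 0.0])
    return Molecule([6, 1, 1, 1], _ang(coords), 0, 2)


_BUILDERS = {
    "h2": _h2,
    "h2o": _h2o,
    "nh3": _nh3,
    "ch4": _ch4,
    "h2co": _h2co,
    "ch3": _ch3,
    "h2o+": lambda: _h2o(charge=1, multiplicity=2),
}


def available():
    return sorted(_BUILDERS)


def molecule(name: str) -> Molecule:
    try:
        return _BUILDERS[name.lower()]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {available()}") \
            from None


def radical_pairs():
    """(neutral, radical cation) pairs at identical geometries.

    Restricted to molecules whose HOMO is non-degenerate and carries weight
    on every atom, so ionization perturbs every atomic density: NH3 (a1 lone
    pair) and H2CO (in-plane O lone pair).  H2O is deliberately absent: its
    b1 HOMO is the out-of-plane O lone pair with a symmetry node at both
    hydrogens, so the H atomic densities are exactly unchanged by
    ionization; CH4 is absent because its t2 HOMO is degenerate and the
    cation's density depends on the tie-break convention.
    """
    out = []
    for name in ("nh3", "h2co"):
        neutral = molecule(name)
        cation = Molecule(neutral.elements, neutral.coords,
                          neutral.charge + 1, 2)
        out.append((neutral, cation))
    return out


def random_molecules(n: int, seed: int = 0, jitter: float = 0.05,
                     templates=("h2o", "nh3", "ch4", "h2co"),
                     charge_states: bool = False):
    """Randomized small molecules from jittered templates.

    ``jitter`` is the Gaussian coordinate noise in Angstrom.  With
    ``charge_states`` every other molecule is the radical cation of its
    geometry, giving a mixed neutral/cation set.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        base = molecule(templates[int(rng.integers(len(templates)))])
        coords = base.coords + rng.normal(
            0.0, jitter / ANGSTROM_PER_BOHR, size=base.coords.shape)
        if charge_states and i % 2 == 1:
            out.append(Molecule(base.elements, coords, base.charge + 1,
                                base.multiplicity % 2 + 1))
        else:
            out.append(Molecule(base.elements, coords, base.charge,
                                base.multiplicity))
    return out
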