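"""Shared fixtures: bases, cached per-molecule pipelines, quadrature grids."""

import numpy as np
import pytest

from spahm import chemio, fixtures
from spahm.densfit import AuxPlacement
from spahm.guess import GuessSpec, guess_density

ALL_ELEMENTS = {1, 6, 7, 8, 16}


@pytest.fixture(scope="session")
def minao():
    return chemio.load_basis("MINAO", ALL_ELEMENTS)


@pytest.fixture(scope="session")
def jkfit():
    return chemio.load_basis("cc-pVDZ/JKFIT", ALL_ELEMENTS)


@pytest.fixture(scope="session")
def bond_basis():
    return chemio.load_bond_basis()


@pytest.fixture(scope="session")
def _pipeline_cache():
    return {}


@pytest.fixture(scope="session")
def pipeline(minao, jkfit, _pipeline_cache):
    """pipeline(name, guess="sad_fock", aux=False) -> (mol, bundle, density).

    Heavy integral work is computed once per (molecule, guess, aux) and
    shared across the whole session.
    """
    def get(name, guess="sad_fock", aux=False):
        key = (name, guess, aux)
        if key not in _pipeline_cache:
            mol = fixtures.molecule(name)
            placement = ()
            if aux:
                placement = AuxPlacement.on_atoms(mol, jkfit).placement_arg
            bundle = chemio.compute_integrals(mol, minao, placement)
            sd = guess_density(mol, minao, bundle, GuessSpec(guess))
            _pipeline_cache[key] = (mol, bundle, sd)
        return _pipeline_cache[key]
    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20240116)


@pytest.fixture()
def random_rotation(rng):
    A, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(A) < 0:
        A[:, 0] *= -1
    return A


def gl_grid(L=8.0, n=64):
    """Tensor-product midpoint cube [-L, L]^3: (points, weights).

    The midpoint rule is spectrally accurate for analytic integrands that
    decay inside the box (Gaussians), unlike end-clustered Gauss nodes.
    """
    h = 2.0 * L / n
    x = -L + (np.arange(n) + 0.5) * h
    P = np.stack(np.meshgrid(x, x, x, indexing="ij"), -1).reshape(-1, 3)
    W = np.full(len(P), h ** 3)
    return P, W
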