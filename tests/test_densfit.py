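"""Density fitting: optimality, center splitting, bond frames."""

import numpy as np
import pytest

from spahm import fixtures
from spahm.chemio import Molecule, bond_basis_entry, compute_integrals
from spahm.densfit import AuxPlacement, build_bond_frame, coeffs_by_shell, \
    fit_bond_density, fit_density, rotate_to_frame, split_by_center
from spahm.guess import GuessSpec, guess_density
from spahm.harmonics import eval_solid_harmonics
from spahm.invariants import atomic_invariant_vector, radial_overlap_blocks
from spahm.partition import partition_density


@pytest.fixture(scope="module")
def h2o_fit(minao, jkfit):
    """Water, sad_fock guess, oxygen atomic density fitted on all atoms."""
    mol = fixtures.molecule("h2o")
    aux = AuxPlacement.on_atoms(mol, jkfit)
    bundle = compute_integrals(mol, minao, aux.placement_arg)
    sd = guess_density(mol, minao, bundle, GuessSpec())
    part = partition_density(sd.D_total, bundle.S, bundle.ao_map, 3)
    fit = fit_density(part.atom_blocks[0], aux, bundle)
    return mol, aux, bundle, part, fit


class TestFitDensity:
    def test_zero_density_zero_coefficients(self, h2o_fit):
        _, aux, bundle, _, _ = h2o_fit
        fit = fit_density(np.zeros_like(bundle.S), aux, bundle)
        assert np.abs(fit.coeffs).max() == 0.0

    def test_fit_is_coulomb_metric_optimum(self, h2o_fit, rng):
        """20 random perturbations of the solution never lower the error."""
        _, aux, bundle, _, fit = h2o_fit
        c, J2c, b = fit.coeffs, bundle.J2c, fit.rhs
        err0 = c @ J2c @ c - 2 * c @ b
        for _ in range(20):
            d = rng.standard_normal(c.size)
            d *= 1e-3 / np.linalg.norm(d)
            cp = c + d
            assert cp @ J2c @ cp - 2 * cp @ b >= err0 - 1e-12

    def test_fitted_electron_count(self, h2o_fit, bond_basis, jkfit):
        """s-moment of the fitted rho_O matches its Lowdin population."""
        mol, aux, bundle, part, fit = h2o_fit
        # int phi_a dr for normalized s shells: sum_k d_k (pi/a_k)^{3/2}/sqrt(4pi)
        moment = 0.0
        i = 0
        for pos, specs in zip(aux.positions, aux.specs):
            for sp in specs:
                if sp.l == 0:
                    from spahm.integrals import PlacedShell
                    ps = PlacedShell(0, sp.exponents, sp.contraction, pos)
                    s_int = float(np.sum(
                        ps._d * (np.pi / ps.exps) ** 1.5)) / np.sqrt(4 * np.pi)
                    moment += fit.coeffs[i] * s_int
                i += 2 * sp.l + 1
        pop = part.lowdin_population(0, bundle.ao_map)
        assert abs(moment - pop) < 0.05

    def test_translation_leaves_coefficients(self, minao, jkfit):
        mol = fixtures.molecule("h2o")
        out = []
        for m in (mol, mol.translated([2.0, -1.0, 3.0])):
            aux = AuxPlacement.on_atoms(m, jkfit)
            bundle = compute_integrals(m, minao, aux.placement_arg)
            sd = guess_density(m, minao, bundle, GuessSpec("gwh"))
            part = partition_density(sd.D_total, bundle.S, bundle.ao_map, 3)
            out.append(fit_density(part.atom_blocks[0], aux, bundle).coeffs)
        assert np.abs(out[0] - out[1]).max() < 1e-9


class TestSplitByCenter:
    def test_exact_partition(self, h2o_fit):
        _, aux, _, _, fit = h2o_fit
        parts = split_by_center(fit, aux)
        assert sorted(parts) == [0, 1, 2]
        assert np.abs(np.concatenate([parts[i] for i in sorted(parts)])
                      - fit.coeffs).max() == 0.0

    def test_mirror_hydrogens_give_identical_invariants(self, h2o_fit, jkfit):
        """H1 and H2 tails of rho_O are mirror images: same invariants."""
        _, aux, _, _, fit = h2o_fit
        blocks = radial_overlap_blocks(jkfit.for_element(1))
        v1 = atomic_invariant_vector(coeffs_by_shell(fit.coeffs, aux, 1),
                                     blocks)
        v2 = atomic_invariant_vector(coeffs_by_shell(fit.coeffs, aux, 2),
                                     blocks)
        assert np.abs(v1.values - v2.values).max() < 1e-8


class TestBondFrame:
    def test_midpoint_and_axis(self):
        mol = Molecule([1, 1], [[0, 0, 0], [0, 0, 2.0]])
        f = build_bond_frame(mol, 0, 1)
        assert np.allclose(f.origin, [0, 0, 1.0])
        assert np.allclose(f.z_axis, [0, 0, 1.0])
        R = f.rotation
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-12
        assert np.linalg.det(R) > 0

    def test_argument_order_is_canonicalized(self):
        mol = Molecule([6, 1, 1, 1, 1],
                       np.array([[0, 0, 0], [1, 1, 1], [1, -1, -1],
                                 [-1, 1, -1], [-1, -1, 1]]) * 1.2)
        f1 = build_bond_frame(mol, 0, 1)
        f2 = build_bond_frame(mol, 1, 0)
        assert f1.atoms == f2.atoms == (0, 1)     # carbon (Z=6) first
        assert np.abs(f1.rotation - f2.rotation).max() == 0.0
        assert np.allclose(f1.z_axis, np.array([1, 1, 1]) / np.sqrt(3))

    def test_coincident_atoms_rejected(self):
        mol = Molecule([1, 1], [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            build_bond_frame(mol, 0, 1)


class TestBondFit:
    def test_bond_along_z_identity_rotation(self, minao, bond_basis):
        """A z-aligned homonuclear bond: lab and local coefficients equal."""
        mol = fixtures.molecule("h2")
        bundle = compute_integrals(mol, minao, ())
        sd = guess_density(mol, minao, bundle, GuessSpec())
        part = partition_density(sd.D_total, bundle.S, bundle.ao_map, 2)
        frame = build_bond_frame(mol, 0, 1)
        entry = bond_basis_entry(bond_basis, 1, 1)
        fit, c_local, aux = fit_bond_density(part.bond_blocks[(0, 1)], frame,
                                             entry, mol, minao)
        assert np.allclose(frame.z_axis, [0, 0, 1])
        assert np.abs(c_local - fit.coeffs).max() < 1e-10

    def test_zero_bond_block_zero_coefficients(self, minao, bond_basis):
        mol = fixtures.molecule("h2")
        bundle = compute_integrals(mol, minao, ())
        frame = build_bond_frame(mol, 0, 1)
        entry = bond_basis_entry(bond_basis, 1, 1)
        _, c_local, _ = fit_bond_density(np.zeros_like(bundle.S), frame,
                                         entry, mol, minao)
        assert np.abs(c_local).max() == 0.0

    def test_rigid_rotation_leaves_local_coefficients(self, minao,
                                                      bond_basis,
                                                      random_rotation):
        """Frame-intrinsic coefficients of an O-H bond are rotation
        invariant up to the azimuthal freedom (checked through the
        m-resolved magnitudes)."""
        mol = fixtures.molecule("h2o")
        out = []
        for m in (mol, mol.rotated(random_rotation)):
            bundle = compute_integrals(m, minao, ())
            sd = guess_density(m, minao, bundle, GuessSpec("gwh"))
            part = partition_density(sd.D_total, bundle.S, bundle.ao_map, 3)
            frame = build_bond_frame(m, 0, 1)
            entry = bond_basis_entry(bond_basis, 8, 1)
            _, c_local, aux = fit_bond_density(part.bond_blocks[(0, 1)],
                                               frame, entry, m, minao)
            by_shell = coeffs_by_shell(c_local, aux, 0)
            mags = []
            for l, C in sorted(by_shell.items()):
                C = np.atleast_2d(C)
                for mm in range(l + 1):
                    if mm == 0:
                        mags.append(C[:, l] ** 2)
                    else:
                        mags.append(C[:, l + mm] ** 2 + C[:, l - mm] ** 2)
            out.append(np.concatenate(mags))
        assert np.abs(out[0] - out[1]).max() < 1e-8

    def test_rotate_to_frame_matches_pointwise_density(self, bond_basis,
                                                       rng):
        """Coefficient rotation reproduces function values at mapped points."""
        entry = bond_basis_entry(bond_basis, 1, 1)
        aux = AuxPlacement.at_point([0.0, 0.0, 0.0], entry)
        from spahm.chemio import place_aux_shells
        shells, _ = place_aux_shells(aux.placement_arg)
        from spahm.integrals import eval_on_grid
        c = rng.standard_normal(aux.n_aux)
        U, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(U) < 0:
            U[:, 0] *= -1
        cr = rotate_to_frame(c, aux, U)
        pts = rng.standard_normal((20, 3))
        f_lab = eval_on_grid(shells, pts) @ c
        f_loc = eval_on_grid(shells, pts @ U.T) @ cr
        assert np.abs(f_lab - f_loc).max() < 1e-10
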