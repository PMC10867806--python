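"""Power-spectrum invariants vs SO(3)/SO(2) quadrature oracles."""

import numpy as np
import pytest

from spahm.chemio import ShellSpec
from spahm.harmonics import rotated_coeffs, zrot_coeffs
from spahm.invariants import atomic_invariant_vector, atomic_layout, \
    bond_invariant_vector, bond_layout, cross_l_pair_count, \
    radial_overlap_blocks, simplified_bond_vector, so2_overlap_oracle, \
    so3_overlap_oracle, truncate_bond_entry

SPECS = [ShellSpec(0, [0.5], [1.0]), ShellSpec(0, [1.7], [1.0]),
         ShellSpec(1, [0.8], [1.0]), ShellSpec(2, [1.1], [1.0])]


@pytest.fixture(scope="module")
def blocks():
    return radial_overlap_blocks(SPECS)


def draw(rng):
    return {0: rng.standard_normal((2, 1)), 1: rng.standard_normal((1, 3)),
            2: rng.standard_normal((1, 5))}


class TestRadialOverlaps:
    def test_single_s_is_unity(self):
        S = radial_overlap_blocks([ShellSpec(0, [0.9], [1.0])])
        assert np.allclose(S[0], [[1.0]])

    def test_two_s_closed_form(self):
        a, b = 0.5, 1.7
        S = radial_overlap_blocks([ShellSpec(0, [a], [1.0]),
                                   ShellSpec(0, [b], [1.0])])
        ref = (2 * np.sqrt(a * b) / (a + b)) ** 1.5
        assert abs(S[0][0, 1] - ref) < 1e-12

    def test_gram_psd(self, jkfit):
        for z in (1, 8):
            for l, S in radial_overlap_blocks(jkfit.for_element(z)).items():
                assert np.linalg.eigvalsh(S).min() > -1e-12


class TestAtomicVector:
    def test_single_s_coefficient_squares(self):
        S = radial_overlap_blocks([ShellSpec(0, [0.9], [1.0])])
        v = atomic_invariant_vector({0: [[2.5]]}, S)
        assert np.allclose(v.values, [2.5 ** 2])

    def test_pure_p_rotation_invariant(self, rng, random_rotation):
        S = radial_overlap_blocks([ShellSpec(1, [0.8], [1.0])])
        c = rng.standard_normal(3)
        v1 = atomic_invariant_vector({1: [c]}, S)
        v2 = atomic_invariant_vector({1: [rotated_coeffs(c, 1,
                                                         random_rotation)]}, S)
        assert np.abs(v1.values - v2.values).max() < 1e-12

    def test_dot_products_match_so3_oracle(self, blocks, rng):
        """The module's core identity over 50 random coefficient draws."""
        for _ in range(50):
            cA, cB = draw(rng), draw(rng)
            dot = atomic_invariant_vector(cA, blocks).values @ \
                atomic_invariant_vector(cB, blocks).values
            oracle = so3_overlap_oracle(cA, cB, blocks)
            assert abs(dot - oracle) / max(abs(oracle), 1e-12) < 1e-6

    def test_oracle_grid_convergence(self, blocks, rng):
        cA, cB = draw(rng), draw(rng)
        o1 = so3_overlap_oracle(cA, cB, blocks, (10, 10, 10))
        o2 = so3_overlap_oracle(cA, cB, blocks, (20, 20, 20))
        assert abs(o2 - o1) < 1e-8

    def test_spherical_only_closed_form(self, rng):
        """s-only content: the average is the plain squared overlap."""
        S = radial_overlap_blocks(SPECS[:2])
        cA = {0: rng.standard_normal((2, 1))}
        cB = {0: rng.standard_normal((2, 1))}
        direct = float(cA[0][:, 0] @ S[0] @ cB[0][:, 0]) ** 2
        assert abs(so3_overlap_oracle(cA, cB, S, (4, 4, 4)) - direct) < 1e-12
        assert abs(atomic_invariant_vector(cA, S).values
                   @ atomic_invariant_vector(cB, S).values - direct) < 1e-12

    def test_identical_inputs_nonnegative(self, blocks, rng):
        c = draw(rng)
        assert so3_overlap_oracle(c, c, blocks) >= 0.0

    def test_gram_of_vectors_psd(self, blocks, rng):
        V = np.array([atomic_invariant_vector(draw(rng), blocks).values
                      for _ in range(8)])
        assert np.linalg.eigvalsh(V @ V.T).min() > -1e-8


class TestBondVector:
    def test_single_s_coefficient_square(self):
        S = radial_overlap_blocks([ShellSpec(0, [0.9], [1.0])])
        v = bond_invariant_vector({0: [[1.7]]}, S)
        assert np.allclose(v.values, [1.7 ** 2])

    def test_axial_rotation_invariance(self, blocks, rng):
        c = draw(rng)
        cz = {l: np.vstack([zrot_coeffs(r, l, 0.77)
                            for r in np.atleast_2d(c[l])]) for l in c}
        v1 = bond_invariant_vector(c, blocks).values
        v2 = bond_invariant_vector(cz, blocks).values
        assert np.abs(v1 - v2).max() < 1e-12

    def test_dot_products_match_so2_oracle(self, blocks, rng):
        for _ in range(50):
            cA, cB = draw(rng), draw(rng)
            dot = bond_invariant_vector(cA, blocks).values @ \
                bond_invariant_vector(cB, blocks).values
            oracle = so2_overlap_oracle(cA, cB, blocks)
            assert abs(dot - oracle) / max(abs(oracle), 1e-12) < 1e-8

    def test_symmetric_only_construction_would_fail(self, blocks, rng):
        """Dropping the antisymmetric blocks breaks the oracle identity:
        the cross term is measurably nonzero for generic coefficients."""
        deviations = []
        for _ in range(10):
            cA, cB = draw(rng), draw(rng)
            vA = bond_invariant_vector(cA, blocks)
            vB = bond_invariant_vector(cB, blocks)
            sym = [i for i, s in enumerate(vA.layout.slots) if s[4] == "sym"]
            dot_sym = vA.values[sym] @ vB.values[sym]
            deviations.append(abs(dot_sym - so2_overlap_oracle(cA, cB,
                                                               blocks)))
        assert max(deviations) > 1e-3

    def test_oracle_grid_convergence(self, blocks, rng):
        cA, cB = draw(rng), draw(rng)
        o1 = so2_overlap_oracle(cA, cB, blocks, 32)
        o2 = so2_overlap_oracle(cA, cB, blocks, 64)
        assert abs(o2 - o1) < 1e-10


class TestSimplifiedVectors:
    def test_m0_only_matches_full_m0_slots(self, blocks, rng):
        c = draw(rng)
        full = bond_invariant_vector(c, blocks)
        m0 = simplified_bond_vector(c, blocks, "m0_only")
        ix = [i for i, s in enumerate(full.layout.slots) if s[1] == 0]
        assert m0.values.size == len(ix)
        assert np.abs(full.values[ix] - m0.values).max() < 1e-12

    def test_m0_only_equals_full_without_m_content(self, rng):
        S = radial_overlap_blocks(SPECS[:2])
        c = {0: rng.standard_normal((2, 1))}
        full = bond_invariant_vector(c, S)
        m0 = simplified_bond_vector(c, S, "m0_only")
        assert np.abs(full.values - m0.values).max() == 0.0

    def test_single_orbital_modes(self, bond_basis, rng):
        from spahm.chemio import bond_basis_entry
        entry = bond_basis_entry(bond_basis, 1, 1)
        for mode, l in (("single_s", 0), ("single_p", 1)):
            kept = truncate_bond_entry(entry, mode)
            assert len(kept) == 1 and kept[0].l == l
            S = radial_overlap_blocks(kept)
            c = {l: rng.standard_normal((1, 2 * l + 1))}
            v = simplified_bond_vector(c, S, mode)
            assert v.values.shape == (1,)
            assert abs(v.values[0] - c[l][0, l] ** 2) < 1e-12
        with pytest.raises(ValueError):
            simplified_bond_vector({0: [[1.0]]},
                                   radial_overlap_blocks(SPECS[:1]), "nope")


class TestLayouts:
    def test_lengths_are_deterministic_shell_pair_counts(self, jkfit):
        # H: 4s3p2d -> 10 + 6 + 3 same-l pairs
        assert atomic_layout(jkfit.for_element(1)).length == 19
        # C: 9s7p5d3f -> 45 + 28 + 15 + 6
        assert atomic_layout(jkfit.for_element(6)).length == 94
        # cross-l accounting variant: all shell pairs
        assert cross_l_pair_count(jkfit.for_element(1)) == 45

    def test_bond_layout_counts(self, bond_basis):
        from spahm.chemio import bond_basis_entry
        entry = bond_basis_entry(bond_basis, 1, 1)
        lay = bond_layout(entry)
        # 6 shells per l, l<=2: m=0: 18*19/2; m=1: 12^2; m=2: 6^2
        assert lay.length == 171 + 144 + 36
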