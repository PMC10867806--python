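# spahm

Local, electron-density-based molecular representations — SPAHM(a) and
SPAHM(b) — for kernel-based machine learning of atomic properties of
neutral, charged and open-shell molecules, together with the kernel ridge
regression (KRR) pipeline that consumes them.

Structure-only descriptors (aSLATM, SOAP, ...) are functions of nuclear
charges {Z_I} and positions {R_I} alone, so a molecule and its radical
cation get the *same* representation and properties that depend on charge or
spin state cannot be learned.  SPAHM(a,b) fix this at minimal cost: a
lightweight one-electron **guess Hamiltonian** (the kind used to start an
SCF, here core / GWH / a one-shot Fock over superposed atomic densities, or
any user-supplied matrix) is diagonalized **once** — no SCF — and the
resulting spin-resolved density matrices are turned into per-atom feature
vectors.

## The construction

For a molecule with guess density **D** (per spin channel σ):

1. **Löwdin partition** — with D̃ = S¹ᐟ²DS¹ᐟ², the diagonal atom blocks give
   atomic densities ρ_I and the symmetrized off-diagonal blocks give bond
   densities ρ_IJ; the decomposition ρ = Σ_I ρ_I + Σ_{I<J} ρ_IJ is exact.
2. **Density fitting** — ρ_I is expanded on atom-centered auxiliary
   functions on *all* atoms (Coulomb metric), giving coefficients c_J(I)
   per center J; ρ_IJ is expanded on a basis at the bond midpoint and
   expressed in a canonical bond-local frame (z along the bond).
3. **Symmetry-adapted vectors** — the similarity of two fitted densities,
   averaged over rotations, is written exactly as a dot product:

   * atoms (SO(3) average): with per-l coefficient matrices C^l and radial
     overlaps S^l,  v = ⊕_l (2l+1)^{-1/2} vech(S^{l,1/2} C^l C^{lT} S^{l,1/2})
     — the SOAP-style power spectrum of the fitted density, satisfying
     v_A·v_B = ∫_SO(3) |⟨ρ_A|R̂ρ_B⟩|² dR̂;
   * bonds (SO(2) average about the bond axis): per |m|, both the symmetric
     and the antisymmetric quadratic blocks of the (c_m, c_{-m}) doublets
     (see `docs/methods.md` for the derivation), satisfying the analogous
     axial-average identity.

   Both identities are enforced in the test suite against brute-force
   quadrature oracles over Euler angles.
4. **Bagging** — per-center vectors are grouped by element (atoms) or by
   partner element (bonds), summed within each bag, and concatenated in
   ascending Z with zero blocks for absent elements, so every atom in a
   dataset gets a fixed-length vector x_I.  Open-shell molecules use the
   concatenation [x_I^α ‖ x_I^β], which is what separates charge states.
5. **Regression** — per element, KRR with Laplacian or Gaussian kernels,
   hyperparameters from an exhaustive grid search under 5-fold
   cross-validation, learning curves by repeated (5×) random subsampling
   against a fixed 20% test split; mean absolute error throughout.

## Worked example

Distinguishing ammonia from its radical cation at the identical geometry:

```python
import numpy as np
from spahm import fixtures, load_basis, Molecule
from spahm.assembly import represent_dataset
from spahm.guess import GuessSpec

neutral = fixtures.molecule("nh3")
cation = Molecule(neutral.elements, neutral.coords, charge=1, multiplicity=2)

minao = load_basis("MINAO", set(neutral.elements))
jkfit = load_basis("cc-pVDZ/JKFIT", set(neutral.elements))

reps, layout = represent_dataset([neutral, cation], minao, mode="a",
                                 aux_basis=jkfit,
                                 guess_spec=GuessSpec("sad_fock"))
print(f"spin mode: {layout.spin_mode}, vector length: {layout.total_length}")
for atom, (r0, r1) in enumerate(zip(reps[0], reps[1])):
    d = np.abs(r0.values - r1.values).sum()
    print(f"atom {atom}: |x_neutral - x_cation|_1 = {d:.4f}")
```

prints

```
spin mode: alpha_beta, vector length: 226
atom 0: |x_neutral - x_cation|_1 = 4.9400
atom 1: |x_neutral - x_cation|_1 = 0.0039
atom 2: |x_neutral - x_cation|_1 = 0.0039
atom 3: |x_neutral - x_cation|_1 = 0.0039
```

The mixed neutral/cation set automatically switches to α/β concatenation
(vector length doubles to 226 = 2 × (19 + 94)), every atom's vector shifts
on ionization — most strongly the nitrogen carrying the hole — and a
structure-only descriptor would give exactly zero for all four atoms.

The same workflow is available from the shell:

```sh
spahm repr-a --xyz-dir molecules/ --guess sad_fock --out reps.h5
spahm train --reps reps.h5 --targets charges.csv --element 7 --out model.h5
spahm predict --model model.h5 --reps new.h5 --out pred.csv
```

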