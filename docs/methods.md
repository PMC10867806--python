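# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order the pipeline applies them, and states what the
bundled data and the synthetic experiments do and do not establish.

## Conventions

All internal lengths are Bohr (XYZ I/O converts from Ångström, factor
0.52917721092 Å/Bohr) and energies Hartree.  Basis functions are pure
(spherical) Gaussians — never Cartesian — over real spherical harmonics
with m ordered −l…+l; the `AOIndexMap` attached to every integral bundle is
the single source of truth for this ordering.  The real solid harmonics are
generated by the standard two-term recursions and verified against an
independent reference implementation in the tests; their rotation matrices
are obtained by solving the (exactly consistent) linear system
S_lm(Uv) = Σ_m′ W_mm′ S_lm′(v) on sample directions, which sidesteps
explicit Wigner-matrix phase conventions.  Every contracted function is
normalized to unit self-overlap, which fixes the overlap diagonal at 1 and
makes all integral tensors convention-free.

The phase convention of the real harmonics is internal only: all shipped
quantities are rotation-averaged quadratic invariants and are provably
phase-independent (the oracle tests would catch any leakage).

## Integrals

Overlap, kinetic, nuclear-attraction and two-/three-/four-center Coulomb
integrals are computed by an in-package McMurchie–Davidson engine (Hermite
expansion coefficients by recursion; Hermite Coulomb tensors from the Boys
function, evaluated via the confluent hypergeometric function).  The engine
is written for the problem sizes this package targets — minimal orbital
bases and fitting bases on a handful of centers — with shell-pair loops in
Python and numpy inside.  It is validated in the test suite against
independent routes: midpoint-grid quadrature for overlaps (spectrally
accurate for Gaussians), a radial-grid Rayleigh quotient for the
one-electron Hamiltonian, the erf closed form for s–s repulsion, and
shell-theorem electrostatic potentials (incomplete-gamma closed forms) for
higher angular momenta.

## Guess Hamiltonians

The guess is diagonalized once against the overlap matrix; there is no SCF
anywhere.  Available kinds:

* `core` — H = T + V.
* `gwh` — H_μν = ½K(H̄_μμ + H̄_νν)S_μν with K = 1.75, where H̄ is the core
  diagonal **spherically averaged within each shell** (trace over m).  The
  textbook per-m diagonal makes the spectrum depend on the molecule's
  orientation as soon as p shells are present (verified: ~10⁻² Hartree
  eigenvalue shifts for ammonia under rotation), which would leak
  orientation into every downstream feature; shell averaging restores exact
  rotational invariance at the cost of the diagonal being the shell-mean
  rather than the raw core element (they coincide for s shells).
* `sad_fock` (default) — a single Fock build F = T + V + J[D_SAD] −
  ½K[D_SAD] with exact four-center integrals in the minimal basis, where
  D_SAD is the superposition of spherically averaged neutral-atom densities
  (diagonal fractional Aufbau occupations per shell).  No iteration.
* `plugin` — any externally built one-electron matrix
  (`(Molecule, BasisSet, IntegralBundle) → H`), the hook through which
  more elaborate model potentials can be slotted in without changing
  anything downstream; the representation machinery is guess-agnostic.

Occupations: n_α = (n_e + 2S)/2, n_β = (n_e − 2S)/2, filled Aufbau from one
common Hamiltonian for both spins (restricted-open-style; α and β share
spatial orbitals and differ only in counts).  Degeneracies at the Fermi
level are broken by ascending eigenvalue, then eigensolver column order;
representations built on open *degenerate* shells are therefore
convention-dependent and the built-in fixture set avoids them (this is why
the methane radical cation, with its degenerate t₂ hole, is not used as a
test pair).

## Löwdin partitioning

D̃ = S¹ᐟ²DS¹ᐟ² (symmetric eigendecomposition; eigenvalues below 10⁻¹⁰ raise
a linear-dependence error).  Atomic densities keep only the diagonal
Löwdin block; **all** off-diagonal content goes to the bond blocks with the
symmetrizing P_I D̃ P_J + P_J D̃ P_I form, so the decomposition is exact by
construction and the atom- and bond-based representations are strictly
complementary.  Löwdin atomic densities are not pointwise positive; no
clamping is applied — the fitting and the invariants are defined on signed
densities.  Bond blocks are computed for all atom pairs by default; an
optional distance cutoff (Bohr) is exposed for large systems.

## Density fitting

The fit minimizes the Coulomb-metric self-repulsion of the error (solve
J2c·c = b with b_a = Σ_μν D_μν (a|μν)), the standard choice with
JKFIT-type auxiliary bases; the similarity in the next step deliberately
uses the plain overlap metric instead (the similarity is an overlap of
densities).  Fitting bases on nearby centers are near-linearly dependent,
so the metric is inverted by eigenvalue pseudo-inverse with a relative
cutoff of 10⁻⁹ (both here and for the bond fits).

Bond frames: the pair is ordered canonically (higher Z first, ties by lower
atom index), the origin is the midpoint, z points from the first to the
second atom, and x completes the frame by Gram–Schmidt of the Cartesian
axis least aligned with z.  Lab-frame fit coefficients are rotated into
this frame per shell with the real-harmonic rotation matrices, so the
stored bond coefficients are frame-intrinsic up to the azimuthal freedom
that the m-resolved invariants remove.

## Symmetry-adapted vectors

**Atoms.**  With C^l the (shells × m) coefficient matrix of one center and
S^l the same-center radial overlaps, the rotation average of the squared
overlap of two fitted densities placed at a common origin is exactly

    ∫ |⟨ρ_A|R̂ρ_B⟩|² dR̂ = Σ_l (2l+1)⁻¹ ⟨M_A^l, M_B^l⟩_F,
    M^l = S^{l,1/2} C^l C^{lT} S^{l,1/2},

because real Wigner matrices are orthogonal with ∫D^l_ab D^l′_cd =
δ_ll′δ_ac δ_bd/(2l+1).  The feature vector packs each M^l by vech with √2
off-diagonal scaling and weight (2l+1)^{-1/2}, so dot products reproduce
the integral exactly; the linear (non-squared) average would annihilate all
l>0 content and carry no shape information.  Same-l pairs only: different
l do not couple under the rotation average.  (A cross-l pairing variant
exists purely as layout accounting, `invariants.cross_l_pair_count`; it is
not a rotation invariant and is never used for shipped vectors.)

**Bonds.**  For the axial average, group each center's coefficients into
(m, −m) doublets over the combined (shell, l ≥ m) index and set
z_m = S^{m,1/2}(c_m + i c_{−m}).  Writing the φ-rotation as a 2D rotation
by mφ of each doublet and expanding the square,

    (2π)⁻¹ ∫ |⟨ρ_AB|R̂_z(φ)ρ_CD⟩|² dφ = t₀² + ½ Σ_{m>0} |z_m^† w_m|²,

and |z†w|² = ⟨Re Z, Re W⟩ + ⟨Im Z, Im W⟩ with Z = zz†.  Re Z is the
symmetric block c_m c_mᵀ + c_{−m}c_{−m}ᵀ and Im Z the antisymmetric block
c_{−m}c_mᵀ − c_m c_{−m}ᵀ: **both** are needed.  A symmetric-only
construction drops the determinant-like cross term
(a·c)(b·d) − (a·d)(b·c) and is not an exact dot-product rewrite of the
axial average — the test suite demonstrates the deviation explicitly and
enforces the exact identity against an independent φ-quadrature oracle.
Each m > 0 therefore contributes a vech-packed symmetric block and a
packed strict-upper antisymmetric block, both weighted 1/√2; m = 0
contributes its symmetric block with weight 1.

Homonuclear bonds have no preferred direction: the vector is computed for
both z orientations (flip = diag(1,−1,−1) acting on the local
coefficients) and averaged, which makes same-element pairs exactly
permutation invariant.

Simplified bond variants for cheaper models: `m0_only` keeps the m = 0
block (equivalent to fitting with m = 0 functions and dropping the axial
integration), `single_s` / `single_p` truncate the bond basis to one shell
before fitting, giving length-1 vectors.

## Bagging and spin

Bags are ordered by ascending atomic number with a dataset-wide element
set; absent elements contribute zero blocks (required for kernels between
molecules of different composition, and it makes layouts stable across
datasets).  SPAHM(b) bags are indexed by the partner element only — the
central element is implicit because regression models are trained per
element.  Spin handling: `total` uses the spin-summed density (one
channel); `alpha_beta` builds each channel separately and concatenates.
The `auto` mode selects `alpha_beta` as soon as any molecule in the set is
open shell, so mixed neutral/radical sets share one vector length; pure
closed-shell sets use `total`.

A physical caveat on charge-state injectivity: ionizing a molecule changes
only the density of the orbital the electron leaves.  If that orbital has
an exact symmetry node on an atom, that atom's representation is provably
unchanged — e.g. the b₁ HOMO of water (out-of-plane O lone pair) has zero
amplitude on both in-plane hydrogens, so H₂O vs H₂O⁺ differ only on
oxygen.  For generic (e.g. thermally distorted) geometries every atom
shifts; the injectivity fixtures use ammonia and formaldehyde, whose HOMOs
carry weight on every atom.

## Bundled basis data

The registry files are generated stand-ins, labelled as such in their
headers, not the literature data files:

* `MINAO` key → a Slater-fit STO-3G-style minimal basis (three Gaussians
  per Slater function, fitted in-package; the universal 1s expansion
  reproduces the classic published coefficients to 4 decimals) at
  Slater-rule zetas, with the standard minimal composition (H: 1s;
  C,N,O: 2s1p; S: 3s2p).
* `cc-pVDZ/JKFIT` key → an even-tempered, uncontracted auxiliary basis
  whose per-element shell composition follows the cc-pVDZ-JKFIT pattern
  (H: 4s3p2d; C,N,O: 9s7p5d3f; S: 11s9p7d3f1g) with generated exponents.
* `bond-default` key → even-tempered bond basis, l ≤ 2, six exponents per
  l spanning [0.08, 8.0] Bohr⁻², identical for all element pairs.
  Externally optimized bond bases can be loaded from file (keyed by sorted
  element pair "X-Y" with a "default" fallback).

Consequence: per-atom feature counts, which are pure layout arithmetic
over the shell composition (Σ_l n_l(n_l+1)/2 per element bag for the atom
variant), are tied to these compositions — 19 (H), 94 (C, N, O) and 146
(S) per bag, 447 for the five-element closed-shell layout, doubling under
α/β concatenation.  Published counts for the authentic basis files apply
when those files are supplied instead; the machinery is file-driven and
does not care.

## Regression protocol

Laplacian exp(−‖x−y‖₁/σ) and Gaussian exp(−‖x−y‖₂²/2σ²) kernels; dual
solve (K + ηI)w = y by symmetric positive solve with a 10⁻¹² jitter
fallback at η = 0.  Grid search: σ ∈ 2^{−5..15} (21 log₂ points),
η ∈ {10⁻¹⁰, 10⁻⁸, 10⁻⁶, 10⁻⁴}, both kernels, 5-fold cross-validated MAE,
ties (within floating-point tolerance) broken toward larger η then larger
σ.  Learning curves: fixed 20% test split, 5 random subsets per training
size from the 80% pool, mean ± std of MAE.  One global seed drives the
split, the folds and the subsampling.  MAE is the single error metric and
is isolated in one function.

## Synthetic data

The fixture generator emulates a small-organics dataset: equilibrium
geometries of H₂, H₂O, NH₃, CH₄, H₂CO, CH₃•, H₂O⁺• and randomized variants
drawn by template with Gaussian coordinate jitter of σ = 0.05 Å (roughly
thermal displacement amplitudes), optionally alternating neutral and
radical-cation charge states.  The synthetic per-atom targets are smooth
charge- and environment-dependent scalars,
y_I = 0.1 Z_I − 0.05 Σ_{J≠I} Z_J e^{−r_IJ/2 Bohr} + q_mol/N + ε with
ε ~ N(0, 0.01²) (the spin variant scales the same form by the spin excess
and vanishes for closed shells).  These emulate the *smoothness and
charge-dependence* of population-analysis targets, not their physics:
passing regression tests shows the pipeline separates elements,
environments and charge states and that errors fall with training size —
it does not certify accuracy on ab-initio charges, shieldings or real
conformational diversity, and the jittered templates do not probe chemical
variety beyond four heavy-atom environments.

The self-contained experiments run at deliberately small problem sizes —
60 molecules of 3–5 atoms for the learnability study, 1000-point random
grids for the density-decomposition checks — chosen so the full validation
suite runs on a laptop-class single core.

## Known limitations

* Elements through Ar in principle; SAD occupations are tabulated for
  H, C, N, O, S only (extend `guess._SAD_OCC` for more).
* No periodic systems, effective core potentials, or Cartesian-Gaussian
  dialects; f-block is out of scope.
* The LB-type model potential of the original eigenvalue work is not
  re-derived; it enters through the plugin hook.
* The integral engine favours clarity over throughput; molecules beyond a
  few dozen atoms would need a compiled backend.
* Bond-basis optimization is not implemented; optimized bases are loaded
  from file when available.
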