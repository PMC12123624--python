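# Methods

## The model

`empff` implements a short-range machine-learned interatomic potential of
the higher-order equivariant message-passing family (atomic cluster
expansion with learnable radial channels and two message-passing layers).
The total energy of a configuration is a sum of atomic site energies,
which gives linear scaling with system size.

For each atom *i* a local graph is built from all neighbors *j* with
‖**r**_ij‖ ≤ r_cut (periodic images included; cells smaller than 2·r_cut
are handled by explicit image enumeration).  Per layer *t*:

1. **Edge basis.**  Each edge combines a learnable radial function
   R(r_ij) (damped sinusoidal basis → small MLP → C² polynomial cutoff
   envelope), real spherical harmonics Y_l1(r̂_ij) (unit-L2
   normalization, no Condon–Shortley phase, flattened l-ascending /
   m-ascending layout), and the neighbor features h_j,l2, contracted with
   real Clebsch–Gordan coefficients into the one-particle basis
   φ_ij,η1,l3m3.  η1 enumerates the (l1, l2, l3) triples.
2. **Atomic basis.**  φ is summed over the neighborhood (normalized by
   the square root of the average neighbor count estimated from the
   training set) and channel-mixed: the permutation-invariant atomic
   basis A_i.
3. **Product basis.**  Symmetric tensor products of A with itself up to
   ν = 3 factors are contracted with generalized Clebsch–Gordan
   coefficients to definite (L, M): body order up to 4 counting the
   central atom.  The ν = 1 block is A itself; the ν = 3 tree couples
   ((l1 l2) l12) l3 → L with all triangle-allowed intermediates.
4. **Message and update.**  A per-element linear combination of the
   product basis forms the message; the update adds an element-dependent
   linear image of the previous features.  That residual term is omitted
   at the first layer, so an atom with no neighbors carries zero features
   through both layers and its site energy is exactly its fixed reference
   energy E0 — E0 values are inputs, never trained.
5. **Readout.**  Site energies consume only the rotation-invariant
   (l = 0) components: a linear map after layer one and a bias-free
   silu MLP (so MLP(0) = 0) after layer two, plus E0.

With two layers the site energy of an atom depends on atoms up to
exactly 2·r_cut away and on nothing beyond — the receptive field measured
by the acceptance script.

Forces are −∂E/∂x and the stress is the symmetrized virial of the edge
gradients divided by the cell volume.  Both are exact analytic
derivatives: the package carries a hand-written reverse-mode pass
(`Evaluator.backward`) that mirrors the forward computation; no autodiff
framework is used.  All algebra is double precision.

### Real Clebsch–Gordan tables

Real-basis coupling coefficients are constructed numerically as the
one-dimensional null space of the equivariance constraint
(D_l1 ⊗ D_l2) C = C D_l3 stacked over three fixed seeded rotations, with
real Wigner-D blocks obtained by least squares from spherical-harmonic
evaluations.  The result is normalized so Σ_{m1,m2} C² = 1 per m3 and
sign-fixed on the first nonzero entry.  This makes the tables exactly
consistent with the package's own rotation convention by construction;
they are validated against quadrature Gaunt projections, brute-force
orthogonality sums, and closed-form values in the tests.  Since the
choice of real-harmonic sign convention and path ordering only
reparametrizes the learnable weights, any self-consistent convention is
equivalent after training; ours is documented in `so3.py`.

### Hyperparameters

| name | meaning | default (tiny preset) |
|---|---|---|
| r_cut | local-environment cutoff (Å) | 4.5 |
| k | feature channels | 16 |
| L_max | message equivariance order | 1 |
| ν | product-basis correlation order | 3 (fixed) |
| layers | message-passing iterations | 2 (fixed) |
| l_max_ang | edge-harmonic / atomic-basis degree | 1 (tiny), 2 otherwise |
| n_radial_basis | radial basis size | 8 |
| radial_hidden | radial MLP widths | (64,) tiny, (32,) otherwise |
| readout_hidden | readout MLP width | 32 tiny, 16 otherwise |

The S/M/L/24M presets set (r_cut, k, L_max) to (4.5, 96, 0),
(5.0, 128, 1), (5.0, 192, 2) and (6.0, 128, 1).  The `tiny` preset is the
desk-scale model used by the test suite and the parameter-recovery
experiment; its l_max_ang = 1 was chosen because, at k = 16, the extra
angular channels of l_max_ang = 2 slow optimization more than they help
accuracy on the toy labels, while the wider radial and readout MLPs
buy the invariant (energy) resolution the torsion term needs at
negligible cost.

## Training

The loss is
`w_E · mean_configs((ΔE/N)²) + w_F · mean_components(ΔF²)` with defaults
w_E = 1, w_F = 10 (eV units) and an optional late-phase multiplication of
the energy weight (`LossSpec.schedule`), mirroring the standard two-phase
recipe for this model family.  Training is full batch: all gas-phase
configurations are merged into one disjoint graph, so an epoch is a
handful of large vectorized array operations.

Parameter gradients of the energy term come from the reverse-mode pass
seeded with the per-site adjoint.  The force term needs
∂/∂θ Σ v·F = −v·∂²E/∂x∂θ with v the (detached) scaled force error; this
mixed second derivative is evaluated as a central finite difference of
the *energy parameter-gradient* along v (step chosen so the maximum atomic
displacement is 10⁻³ Å).  The O(ε²) error is far below the gradient noise
Adam tolerates, and it vanishes quadratically as the force error shrinks.

Two optimizers are provided: full-batch Adam with cosine learning-rate
decay and global gradient-norm clipping (default, lr 10⁻², clip 10), and
scipy L-BFGS on the same loss (optionally two-phase when a schedule is
set), which converges far deeper on small sets and is what the overfit
capacity test uses.  Model selection tracks a validation score computed
with the *final-phase* loss weights so the retained parameters match the
objective optimized last.  Everything is deterministic given the seed.

Splitting is at the molecule level: conformers of one molecule identity
never appear in more than one of train/validation/test.

## Synthetic labels

The generator stands in for quantum-chemistry reference data with an
analytic classical potential: harmonic bonds (k = 30 eV/Å²) and angles
(k = 3 eV/rad², θ0 = 104.5°), a 3-fold cosine torsion (V = 0.1 eV
≈ 2.3 kcal/mol), and an intermolecular Morse-style well (ε = 0.01 eV,
σ = 3.2 Å) truncated smoothly at r_t = 4.2 Å — strictly inside the 4.5 Å
model cutoff, so a short-range model can represent the potential exactly
and parameter recovery probes the architecture and the training loop
rather than missing physics.  Toy molecules use two elements (z = 8, 1);
conformers are drawn by random perturbation plus short seeded Langevin
dynamics at 300 K and 500 K, mirroring the two-temperature sampling style
of the real training sets.  Dataset kinds: monomers, dimers, clusters,
periodic liquid boxes, and simple-cubic molecular crystals, each with
exact analytic forces (finite-difference-verified at generation time) and
stress for periodic records.

What the toy data do **not** emulate: electrostatics and dispersion
tails, charge transfer, bond breaking, conformational diversity of real
drug-like molecules, and label noise.  Passing the recovery test
therefore shows the model/training machinery can represent and learn a
smooth short-ranged many-body surface from energy+force labels — not that
it reaches any particular accuracy on real quantum-chemistry data.

By default the labeler derives bonds from covalent radii (scale 1.2) per
configuration.  For geometry optimization and dihedral scans the bond
graph must be frozen (`ToyPotential(topology=...)`): with a
geometry-dependent topology an optimizer can lower the energy
discontinuously by stretching a bond until it "breaks".

## Evaluation metrics

* Per-atom energy RMSE (meV/atom; errors normalized per atom before
  squaring) and force RMSE over all Cartesian components (meV/Å).
* Intermolecular forces: per molecule, the least-squares projection of
  its atomic forces onto the 6-dimensional rigid-body space (3
  translations, 3 rotations about the center of mass; rank-revealing for
  linear molecules).  Unit weighting by default — mass weighting is a
  flag, since conventions differ — with the residual defined as the
  orthogonal (intramolecular) complement.
* Torsion profiles are min-shifted to zero; the barrier height is the
  global maximum of the shifted profile.  Per-well barriers are a
  deliberate non-goal.
* Scan geometry RMSD uses optimal rigid superposition (Kabsch, proper
  rotations only), no atom reordering, averaged over the scan grid.

## Simulation protocols

* Geometry optimization: scipy L-BFGS on E with analytic gradients,
  converged when max |F| (including restraint forces) ≤ fmax (default
  0.01 eV/Å).  Dihedral restraints are stiff harmonics (default
  1000 kcal/mol/rad²) rather than exact constraints — simpler, and the
  relaxed dihedral tracks the target to < 0.5° at that stiffness.
* Dihedral scans walk a 24-point, 15°-spaced grid, each point restarting
  from the previous relaxed geometry.
* MD: velocity Verlet (NVE); BAOAB Langevin (NVT; γ = 0 reduces exactly
  to velocity Verlet, which the tests assert step-for-step); NPT adds
  isotropic Monte-Carlo volume moves in ln V with the standard
  exp[−β(ΔU + PΔV) + (N+1)Δln V] acceptance — an exact target ensemble
  with a single move-size parameter.  All noise streams are seeded.
* RDF: minimum-image pair histogram with shell-volume/ideal-gas
  normalization; r_max is validated against half the smallest cell width.
* ΔH_vap = ⟨E_gas⟩ − ⟨E_liq⟩/N_mol + RT and ΔH_sub = E_gas − E_cry/Z
  + 2RT (quasi-harmonic protocol constant).  Both formulas are declared
  protocol choices of this package; uncertainties come from block
  averaging.
* The vibrational power spectrum is the mass-weighted, Hann-windowed
  velocity periodogram (Wiener-Khinchin form of the VACF transform),
  normalized so its integral over wavenumber equals the mass-weighted
  mean-square velocity (Parseval-checked in the tests).

## Numerical choices and degenerate inputs

* Neighbor lists include pairs at exactly r_cut; the smooth envelope
  vanishes there, so the boundary convention is numerically immaterial.
* Segment sums over sorted edge lists use `reduceat`; edge ordering is
  deterministic (sorted by (i, j, shift)), so results are reproducible
  bit-for-bit across runs.
* Dihedral gradients are guarded against the colinear degeneracy by
  flooring the squared normal lengths; the rigid-body projection handles
  linear molecules through a rank-revealing least-squares solve.
* Weight initialization is scaled-Gaussian, seed-controlled; pooling is
  normalized by √(average neighbor count).

## Problem sizes used by the shipped experiments

The parameter-recovery experiment trains the `tiny` preset on 500
monomer conformers (400/50/50 after molecule-level splitting) for 400
full-batch Adam epochs with late-phase energy up-weighting; the overfit
capacity check runs two-phase L-BFGS on 10 configurations; the MD
integrity checks integrate a single toy molecule for 10 ps at 0.5 fs.
These sizes were chosen as the smallest at which the respective
properties are cleanly resolved.

## Known limitations

* Neutral, closed-shell systems only; no explicit long-range
  electrostatics or dispersion — interactions beyond 2·r_cut are invisible
  by construction.
* The numpy evaluator is vectorized but single-threaded; it targets
  desk-scale systems (≲ 10³ atoms), not production MD.
* l_max_ang ≤ 3 (the degree with hardcoded analytic Cartesian
  gradients); ν is fixed at 3 and the layer count at 2, as in the model
  family this implements.
* The NPT barostat scales atomic positions affinely (not molecule-wise),
  which is adequate for the toy systems it is used on here.
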