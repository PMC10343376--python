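# Methods

This note records the models implemented in `xbir3`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the procedure was genuinely
open.

## End-point free-energy model

The per-snapshot estimate is ΔG = E_inte + ΔG_polar + ΔG_nonpolar − TΔS.
Only the complex ensemble is used: free receptor and ligand coordinates
are obtained from each complex frame by deleting the other segment's
atoms, so every intramolecular MM term cancels between bound and free
states and only the inter-segment interaction energy survives.  Ensemble
results are reported as mean ± standard deviation of the per-frame
totals; the **population** convention (divide by n) is used for the ± and
recorded in every output's metadata.  The entropy term is a single
ensemble-level number added to the mean, not a per-frame quantity.

### Molecular-mechanics interaction energy

Exact pairwise sums, no cutoff: post-processing works on a finite set of
atoms where the O(n²) sum is cheap and switching functions belong to the
MD engine, not the estimator.  The Coulomb constant is fixed at
332.0636 kcal·Å/(mol·e²) (CHARMM convention) and the vacuum dielectric
(ε = 1) is used, matching the simulation convention the ensembles carry.
Lennard-Jones uses the CHARMM ε/rmin form with geometric-mean ε and
additive rmin halves.  Atom pairs closer than 10⁻⁶ Å raise an error
rather than returning an astronomically large number.

### Polar solvation (finite-difference Poisson–Boltzmann)

Linearized PB only, on a uniform grid with a 7-point stencil:

* Unit system: Å, e, kcal/mol; the Poisson equation is scaled so that a
  point charge in dielectric ε has potential 332.0636·q/(ε·r).
* Dielectric boundary: van-der-Waals surface from the per-atom PB radii,
  no probe smoothing.  Each grid edge gets the harmonic mean of ε_in and
  ε_out weighted by the fraction of the edge inside the solute, sampled
  at 9 deterministic points per edge.  Harmonic averaging is what keeps
  the Born-ion error at the sub-percent level (measured 0.5% at 0.4 Å
  spacing, 1.3% at 0.8 Å against the closed form).
* Salt: Debye–Hückel screening κ² = 8π·λ_B·n in solvent-region nodes,
  with λ_B the Bjerrum length at ε_out; default 0.15 M 1:1 electrolyte
  (κ⁻¹ ≈ 8.0 Å at 303.15 K), matching a KCl-neutralized simulation box.
* Boundary condition: Dirichlet values from the single-sphere
  Debye–Hückel potential summed over atoms (plain Coulomb for the
  homogeneous reference solve).
* Solver: Jacobi-preconditioned conjugate gradients to a relative
  residual of 10⁻⁸ (the operator is symmetric positive definite);
  non-convergence raises with the residual.
* Energies: the charging energy is ½Σ qφ with charges spread onto the
  grid by trilinear weights; the solvation energy is the difference
  between the heterogeneous solve and a uniform-ε_in solve **on the same
  grid with the same charge spreading**, so the discrete self-energy
  cancels identically.  A zero-charge system returns exactly 0 without
  solving.

Binding terms use three solves (complex, receptor, ligand) on the grid
derived from the complex, so lattice placement cancels in the
differences.  Default grid: spacing 0.5 Å (0.4 Å for oracle-grade runs,
0.8 Å for test-speed runs), padding 10 Å, never below 8 Å.

### Non-polar solvation

G = 0.00542·SASA + 0.92 kcal/mol per species.  Applying the intercept per
species is a deliberate convention — the binding difference then carries
a constant −0.92 kcal/mol offset, which is surfaced explicitly as an
`offset` row / `nonpolar_offset` field rather than silently absorbed.
SASA is Shrake–Rupley with a deterministic golden-spiral quadrature
(default 960 points; floor 24), probe 1.4 Å, atomic radii = PB radii.
An isolated sphere is exact under this quadrature; the two-sphere
spherical-cap closed form is reproduced within 1%.

### Entropy

**Interaction entropy (IE):** −TΔS = RT·ln⟨exp(ΔE_inte/RT)⟩ with the
series centered first and the exponential average evaluated by
log-sum-exp, so the estimator cannot overflow and is exactly zero for a
constant series.  k_BT is interpreted per mole (RT), consistent with all
other energies.  The estimator is non-negative (Jensen) and converges to
σ²/2RT for Gaussian fluctuations; its sampling variance explodes for
large fluctuations, so a diagnostic warning fires when σ > 3·RT instead
of any silent truncation.

**Normal modes (NM):** each species is minimized (L-BFGS-B) to a gradient
RMS ≤ 10⁻⁵ kcal/mol/Å on a caller-supplied energy function, the Hessian
is built by central finite differences (step 10⁻⁴ Å), mass-weighted and
diagonalized; 6 near-zero modes are removed (5 for linear species), an
imaginary frequency above 1 cm⁻¹ raises "not at a minimum", and the
quantum-harmonic-oscillator entropy is summed over retained modes.  A toy
harmonic bond/angle force field ships for testing; NM on production force
fields is out of scope.

## Trajectory analyses

Core-backbone RMSD uses Kabsch superposition on the backbone of the
structured core (XIAP-BIR3 numbering 259–335; termini 248–258 and
336–352 are excluded as flexible).  Ligand RMSD applies the core
superposition to the ligand heavy atoms; a mean above 2 Å flags the pose
unstable.  The reference is frame 0 unless an external reference is
given.  Two-point selections are superposed by segment-direction
alignment; collinear selections of three or more points are rejected as
degenerate.  Hydrogen bonds use donor–acceptor ≤ 3.5 Å plus a D–H···A
angle ≥ 120° when the hydrogen is specified — these geometric defaults
follow common practice, are config-overridable, and are recorded in every
report.  Contact maps count frames with any residue heavy atom within
4.0 Å of each ligand heavy atom.

## Decomposition

Interaction-energy decomposition is an exact pair assignment: each
receptor–ligand pair term goes to the receptor atom's residue (or the
ligand atom's group), so rows sum to the undecomposed total to machine
precision on every frame.  Polar-solvation attribution is the standard
charge–potential product ½·q_i·Δφ_rf(r_i), where Δφ_rf is the
reaction-field potential difference between the complex solve and the
isolated-species solve read back with the same trilinear weights used to
spread the charges — attribution therefore sums to ΔG_polar *exactly*,
not approximately.  SASA attribution is the per-atom area difference
× 0.00542; the intercepts are excluded from rows and reported as a
separate `offset` row so row sums stay meaningful.  Ligand-atom solvation
attribution appears on a `ligand` row of the per-residue table.

## Pharmacophores

Feature perception on typed ligand atoms: HBD at donor heavy atoms, HBA
at acceptors, HAr at flagged-ring centroids (point features; no plane
normals), H at centroids of bonded clusters of ≥ 3 non-ring carbons.
Structure-based model construction retains a ligand feature only when its
complementary protein condition holds — an H-bond partner within 3.5 Å
for HBD/HBA, a protein heavy atom within 4.0 Å for H/HAr — in at least a
frequency threshold (default 0.5) of frames, with frame-averaged centers;
exclusion volumes sit on protein heavy atoms within 6 Å of the ligand.
Feature tolerance defaults to 1.5 Å and exclusion radii to 1.0 Å; both
are config-overridable.

Matching is a deterministic exhaustive kind-respecting assignment of
model features to ligand feature points, superposed by least squares and
accepted when all assigned pairs fall inside their tolerance spheres and
no ligand heavy atom enters an exclusion volume.  "One omitted feature"
is enumerated exhaustively over every single feature — a deterministic
superset of a screen that discards one feature at random — and reports
record this.  An enumeration above 10⁶ assignments raises rather than
stalls.  Early-recognition AUC ("AUC at 1.5%") is implemented as the
normalized partial AUC over the top fraction of the ranked library
(trapezoid rule through tie groups; a prefix with no inactives scores 1);
the full-library case coincides with Mann–Whitney pair counting with ties
credited ½.  The enrichment factor uses D = A + I, the full labeled
dataset size — with the published confusion counts this reproduces the
reported EF values (32.3, …, 20.4), which the retained-library size does
not.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (recipe, seed):

* **Toy complexes** — an arc of neutral four-atom backbone residues whose
  carbonyl oxygens line a groove holding a net +1 two-group ligand
  (protonated donor nitrogen + carbonyl-like acceptor, mirroring the
  piperazine/carbonyl chemistry of BIR3 groove binders).  Fully
  parameterized, group-tagged, deterministic.
* **Ensembles** — isotropic Gaussian jitter of width σ around the base
  structure.  H-bond schedules are satisfied by explicit frame
  assignment: a seeded permutation picks exactly round(occupancy·n)
  frames in which the acceptor is placed 2.9 Å from the fluctuating
  donor (6.0 Å otherwise), so occupancy recovery is exact to 1/n — e.g.
  0.874 over 2500 frames is 2185 frames by construction.  Defaults
  (20 ps frame spacing, 303.15 K, σ ≈ 0.3 Å) mirror a stable production
  run of a bound complex.
* **Energy series** — i.i.d. Gaussians with specified moments, for
  entropy-estimator oracles.
* **Screening libraries** — planted on a reference model (default
  composition 2 HBD + 1 HBA + 4 H + 1 HAr with exclusion volumes, the
  composition of a merged crystal+ensemble model of a groove binder).
  Actives reproduce every feature with jitter σ = 0.25 Å (validated
  < tolerance, else the recipe is rejected) and pIC50 ~ U(6, 9];
  decoys *lack* 2 planted feature points (deletion is the one corruption
  that survives optimal realignment unconditionally; a single violated
  feature would make every decoy matchable under one omission, so ≥ 2 is
  the default) and carry pIC50 ~ U[3, 4.5); entries in the excluded band
  [4.5, 6] are generated only on request and skipped by screening.  The
  default library sizes follow the published test-chemolibrary
  composition, 173 actives vs 5417 inactives (D = 5590).

None of this emulates force-field dynamics: there are no correlated
motions, no anharmonicity, no conformer strain, no decoy property
matching.  Passing tests therefore demonstrate that the *estimators and
bookkeeping* are correct on ensembles with known ground truth — they do
not certify predictive accuracy on real trajectories, which depends on
sampling and force-field quality that are out of scope here.
Consequently the absolute ΔG_MM-PBSA values of real 50-ns XIAP-BIR3
trajectories are not reproduced anywhere in this package; the benchmark
module consumes such trajectory-averaged values as *inputs* and
reproduces only their downstream arithmetic (conversions, correlations,
screening metrics).

## Degenerate inputs and tie-breaks

Empty selections, single-segment "complexes", unparameterized atoms,
non-positive IC50s, zero-variance correlation inputs, single-class ROC
labels and empty hit lists (EF undefined → None) all raise or flag
explicitly.  Matching tie-breaks: lowest RMSD, then fewest omissions,
then lexicographic omitted label.  Rank concordance treats ties as
neutral and reports them.  The tabulated ΔG_exp of the AVPI tetrapeptide
(−8.91 kcal/mol for 320 nM) disagrees with the RT·ln(IC50) conversion
(−9.00); the benchmark flags this row in its warnings rather than
resolving it, and correlations exclude AVPI by default (flag to include).

## Problem sizes

Default test and acceptance runs use 3–5-residue toy complexes, 1–4-frame
ensembles for PB-bearing stages (0.8 Å spacing, 8 Å padding), 0.4 Å
spacing for the Born oracle, 2500-frame ensembles for occupancy
bookkeeping, 10⁶-sample series for the IE Gaussian limit, and
full-composition (5590-entry) libraries for screening.  These sizes were
chosen so the planted truths are sharp (large n where the check is
statistical, small systems where the check is exact) while the whole
suite stays interactive on one CPU.
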