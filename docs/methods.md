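# Methods

This note documents the models, numerical choices, and open design
decisions behind the package, and what the synthetic test conditions do
and do not establish about behavior on real data.

## Scope and data model

The unit of computation is a `Molecule` (element symbols, Cartesian
coordinates in Å, net formal charge in {−1, 0, +1}, and a bond list with
fractional orders). The neutral input and every generated charge-state
model are both Molecules. Only singly charged species are modeled, and
only nitrogen and oxygen sites are titratable: carbon (de)protonation and
othergen (S, P, Se) titration are deliberately out of scope, matching the
chemistry the energy ranker is meant to be trained on.

## Structure building

SMILES inputs are embedded with RDKit's ETKDGv3 distance geometry
(seeded, deterministic) and relaxed with MMFF94. The relaxation budget is
`max(200, 10 × n_atoms)` steps: the floor guarantees convergence for tiny
molecules, and the linear term grows the budget with size and
rotatable-bond count. XYZ inputs are read verbatim; bonds are then
perceived by a covalent-radius criterion (bonded when r ≤ 1.25 × (rᵢ+rⱼ),
Cordero radii). Distance perception cannot recover bond orders, so
order-sensitive eligibility rules (below) are less discriminating for XYZ
input than for SMILES input; aromatic N–H sites, for example, are only
excluded when aromatic orders are known.

All per-element data (IUPAC masses, Pauling electronegativities, Cordero
covalent radii, Bondi van der Waals radii, recommended static dipole
polarizabilities) are snapshotted in `elements.py` so descriptor values
never drift with dependency versions.

## Site enumeration

Protonation keeps every N with total bond order < 4 — which excludes
quaternary and nitro nitrogen and pyrrole-type aromatic N–H, whose lone
pair sits in the π system — and every O with total bond order ≤ 2. Amide
nitrogen is kept (both amide N and O are common gas-phase protonation
targets). Deprotonation keeps every N–H and O–H group. Sites equivalent
under graph automorphism (detected by Morgan-style iterative neighborhood
refinement) collapse to the lowest-index representative, so the two amine
hydrogens of glycine yield one deprotonation model, not two.

Protons are placed 1.02 Å from N or 0.98 Å from O, opposite the
normalized sum of existing bond vectors (perpendicular fallback for
degenerate geometry). The exact length is immaterial: geometries are
re-optimized downstream.

## Descriptors

The ten features are: CBA polarizability (Å³); |CBA−COM|, |CBA−COE|,
|COM−COE| (Å); the interaction angle; solvent-accessible surface area
(Å²); and the O/N/halogen/othergen counts. Choices where the convention
was genuinely open:

- **Electronegativity scale** for the COE: Pauling, the default
  convention; the scale is a weight table, and since the ranker is always
  retrained on features computed by this code, a different scale would be
  absorbed by training.
- **Angle vertex**: the angle is measured at the COE, between the rays to
  the COM and to the CBA. Degenerate geometry (a ray shorter than 1e-8 Å)
  returns 0 with a flag. The angle is computed with the atan2 form, which
  is well-conditioned at 0° and 180° where the acos form loses ~8 digits.
- **Surface area**: solvent-accessible area, 1.4 Å probe, Shrake–Rupley
  quadrature with 3840 deterministic golden-spiral dots per atom
  (quadrature error ≲ 0.5% against dense references). Each atom's dot
  template is oriented by a local frame built from its nearest neighbors,
  ordered by (distance, index) — both rigid-motion invariants — so the
  descriptor is exactly pose-independent, which principal-axis frames are
  not for near-symmetric rotors. A fixed detuning rotation keeps the
  spiral's structure from aligning with occlusion boundaries at bonded
  neighbors.

All ten descriptors are invariant under rigid motion; the test suite
verifies drift < 1e-6 over 100 random rotations+translations per fixture.

## Energy ranking and pruning

The relative-energy regressor is a gradient-boosted tree ensemble
(scikit-learn), wrapped as an estimator with defaults of 300 trees,
depth 6, learning rate 0.1 — all exposed, so users holding a specific
hyperparameter table can match it. Training splits 20% of *systems* (not
rows) into a held-out set, so no molecule straddles the split; the
held-out RMSE is stored with the model because the pruning heuristic
needs the uncertainty of whatever frozen model is loaded at prediction
time.

The acceptance capacity ∧ = (1/3)(RMSE + RE_min)/(σ + S) is implemented
literally in kcal/mol units. It is dimensionally heterogeneous (an energy
over an energy plus an energy squared) and is treated as what it is — a
heuristic, not a physical quantity. σ and S are population statistics
(ddof = 0), which remain defined for a single-model ensemble; when
σ + S < 1e-9 (one model, or identical predictions) the capacity is set to
1 so exactly the top model advances. The capacity-to-count mapping is
k = clamp(⌈∧⌉, 1, n): the ceiling preserves the safeguard against losing
a true positive, and rank 1 is always forwarded. Rank ties break toward
the lower charge-bearing-atom index, making output deterministic.

Feature importance is mean increase in RMSE (MIR): for each feature,
retrain without it over repeated seeded grouped splits and average
(RMSE_without − RMSE_full). Small negative values for useless features
are ordinary resampling noise.

## Refinement

Forwarded models get a short local minimization — at most 50 iterations
of a monotone steepest-descent minimizer with adaptive step (uphill
trials rejected, step halved; downhill accepted, step grown ×1.2 capped
at 0.2 Å), stopping early below a max-force threshold of ~0.05 eV/Å. The
best-seen geometry is returned, which enforces the descent contract
(refined energy ≤ input single-point energy) by construction. Shallow
optimization is intentional: the goal is comparing models on a common
energy footing without letting structures wander into artifacts.

Potentials are pluggable behind a small contract (supported elements,
single-point energy in kcal/mol, deterministic minimize). The bundled
`toy` backend is a classical pair potential — harmonic bonds with
covalent-radius equilibria (k = 600 kcal/mol/Å²), short-range exponential
repulsion between non-bonded atoms (A = 500 kcal/mol, ρ = 0.35 Å), and a
screened Coulomb term with charges proportional to each atom's
electronegativity offset from the molecular mean (0.2 e per Pauling
unit). It is a real potential with analytic gradients, chosen for
determinism and speed, not for physical fidelity; its element coverage
deliberately mirrors ANI-2x (H, C, N, O, F, Cl, S) so surrogate
substitution is exercised identically. The ANI-2x backend is a thin
optional wrapper requiring `torchani`.

Surrogate substitution maps Br/I → Cl and P/Se → S before optimization
and restores the original symbols (keeping optimized coordinates)
afterwards; anything else outside the potential's coverage is a hard
error. The pipeline-level test that a Br-containing fixture and its
Cl-swapped twin (and an S fixture and its Se twin) assign the same rank-1
charge site checks the end-to-end consequence of this approximation.

Mole fractions are Boltzmann weights over the refined relative energies,
x = exp(−RE/RT)/Σ exp(−RE/RT), with R = 1.98720425864×10⁻³ kcal/(mol·K)
and T = 298.15 K by default (configurable). Final ranks tie-break toward
the better initial rank.

## Synthetic training data

There is no quantum-chemistry-labeled training set in the repository; the
generator stands in for one. Per system it draws 3–8 models with features
sampled over plausible physical spans (distances 0–10 Å, angle 0–180°,
surface area 50–800 Å², counts 0–6), assigns raw energies from a planted
linear signal — by default 3 kcal/mol per Å of CBA–COE distance, a
30 kcal/mol signal range — plus Gaussian noise of 3 kcal/mol (10% of the
range), and re-zeroes labels to the per-system minimum. The noiseless
signal is optionally returned for recovery scoring but never enters the
table.

Two consequences of the per-system re-zeroing are worth knowing. First,
the per-system offset (driven by the minimum draw) is not a function of
any single row's features, so no row-wise regressor can predict it:
held-out RMSE has an irreducible floor (~6% of the label range after
offset correction, ~13% raw, even with zero injected noise), while
within-system *ordering* — the quantity the pipeline actually uses — is
recovered essentially perfectly in the noiseless case. Second, raw
(label − truth) residuals mix the injected noise with that minimum shift;
the injected noise SD is estimated by per-system-centered residuals with
pooled ddof, which the tests verify recovers the nominal value within
10%.

Study-scale checks train on 200 systems (~1100 rows, comparable to a
realistic curated training set for one ion mode) and verify held-out
Spearman ≥ 0.8 against the noiseless signal, mean per-system Kendall
τ ≥ 0.7, and that MIR ranks the planted feature first with an appended
pure-noise feature scoring near zero.

What passing these tests shows: the descriptor pipeline is correct and
pose-invariant, the learner recovers a recoverable signal at realistic
scale, the pruning and refinement machinery behaves as specified, and the
whole pipeline is deterministic. What it does not show: that the ten
descriptors suffice to predict real protonation energetics — that depends
on training labels from quantum chemistry or experiment, which users must
supply through `protomer train`.

## Known limitations

- XYZ input loses bond orders; eligibility rules degrade gracefully but
  enumerate more generously than for SMILES input.
- The toy potential's energies are not comparable across molecules of
  different composition and must not be interpreted physically.
- Protonation eligibility is rule-based (bond-order thresholds, nitro
  exclusion); exotic functional groups may need the rules extended.
- Multiply charged ions, zwitterions, and conformer ensembles per
  protomer are out of scope.
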