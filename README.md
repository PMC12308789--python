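# protomer

Gas-phase protomer enumeration and equilibrium charge-state ranking for
ion-mobility mass spectrometry (IM-MS).

## The problem

Electrospray ionization produces singly charged ions — [M+H]⁺ or [M−H]⁻ —
but a molecule with several basic nitrogens and oxygens can carry that
proton (or lose one) at any of them. Each choice of charge site is a
*protomer*: same formula, same charge, different 3D structure, and
therefore a different collision cross section in an ion-mobility
experiment. Resolving which protomer dominates at equilibrium normally
requires quantum-chemical modeling of every candidate site, which is the
bottleneck of structure-resolved IM-MS workflows. This package screens the
candidates cheaply so that expensive modeling is only ever spent on the
one or two sites that matter.

## The method

For a neutral input molecule **M** and an ion mode, the pipeline:

1. **Enumerates titratable sites** — every N/O that can accept a proton
   (protonation) or every N–H/O–H group (deprotonation); carbon and
   "othergen" (S, P, Se) titration are out of scope, and
   graph-symmetry-equivalent sites are collapsed. Each site yields one
   charge-state model **Z** with formal charge ±1.
2. **Featurizes** each model with 10 rigid-motion-invariant descriptors:
   polarizability of the charge-bearing atom (CBA); the distance triangle
   between the CBA, the center of mass (COM), and the center of
   electronegativity, COE = Σᵢ eᵢrᵢ / Σᵢ eᵢ (Pauling weights); the
   interaction angle ∠(COM, COE, CBA); solvent-accessible surface area
   (Shrake–Rupley, 1.4 Å probe); and the O / N / halogen / othergen
   counts.
3. **Ranks** the models by relative energy RE (kcal/mol) predicted with a
   gradient-boosted-tree regressor; rank r = 1 is the most stable.
4. **Prunes** with the acceptance capacity

   ∧ = (1/3) · (RMSE + RE_min) / (σ + S),

   where RMSE is the regressor's held-out error and σ, S are the standard
   deviation and variance of the predicted REs. The top k = ⌈∧⌉ models
   (clamped to [1, n]) advance — few when the ensemble is confidently
   separated, more when it is noisy or bunched.
5. **Refines** survivors with a short ("soft", 50-step) local geometry
   optimization under a pluggable potential. Elements outside the
   potential's coverage are optimized through surrogate substitution
   (Br/I → Cl, P/Se → S) and switched back afterwards.
6. **Reranks** by refined energy (final Rank R; Rank 1 is the assigned
   equilibrium charge state) and reports Boltzmann mole fractions
   xᵢ = exp(−REᵢ/RT) / Σⱼ exp(−REⱼ/RT) at 298.15 K.

The bundled `toy` backend is a deterministic classical pair potential
covering H, C, N, O, F, Cl, S; an ANI-2x neural-network backend is
available when the optional `torchani` dependency is installed.

## Worked example

Train a ranker on a synthetic labeled table (a stand-in for a
quantum-chemistry-labeled training set, with a planted energy signal) and
rank the protonation models of glycine:

```bash
protomer synth --out table.csv
protomer train --table table.csv --seed 1 --out ranker.joblib
protomer run --input "NCC(=O)O" --mode "[M+H]+" --ranker ranker.joblib \
    --name glycine --seed 1 --out .
```

which prints

```
1074 rows -> table.csv
held-out RMSE: 6.5499 kcal/mol -> ranker.joblib
glycine: 3 model(s) enumerated, 3 refined (capacity 14.039)
Rank 1: O3 (mole fraction 1.0000)
```

and writes `completed/glycine/` containing one XYZ file per ranked model,
a JSON sidecar, and this summary:

```
models enumerated : 3
models forwarded  : 3  (acceptance capacity = 14.0394)

  R   r  CBA       pred RE         RE  mole frac
                  kcal/mol   kcal/mol
------------------------------------------------
  1   2  O3          0.856      0.000     1.0000
  2   3  O4          1.077      6.500     0.0000
  3   1  N0          0.712     12.040     0.0000
```

Glycine's three candidate sites (amine N, carbonyl O, hydroxyl O) were all
forwarded because the first-pass REs are tightly bunched relative to the
ranker's uncertainty (large ∧); after refinement the carbonyl oxygen (O3)
is assigned as the equilibrium charge site with essentially the whole
Boltzmann population. With a ranker trained on real labels the first-pass
REs, and hence the assignment, would reflect that chemistry instead of
the synthetic demonstration signal.

Library use mirrors the CLI: `protomer.run(source, PipelineConfig(...))`,
with `enumerate_models`, `featurize`, `train`, `acceptance_capacity`,
`soft_optimize`, `final_rank`, and `mole_fractions` available
individually. The regressor (`EnergyRegressor`) is a scikit-learn
estimator and composes with sklearn model selection.

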