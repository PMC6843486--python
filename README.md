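# cycloplex

Analysis toolkit for **cyclodextrin host–guest inclusion complexes**:
trajectory-derived geometry and energetics on one side, the experimental
phase-solubility / cytotoxicity analysis chain on the other, exercised
end-to-end on synthetic systems with known ground truth.

## The scientific problem

Cyclodextrins (CDs) are cyclic oligosaccharides of α-D-glucopyranose units
(seven for βCD) whose hydrophobic toroidal cavity can encapsulate poorly
soluble guest molecules — for example a naphthoquinone-like natural product —
improving their aqueous solubility and bioactivity. Characterizing such an
inclusion complex combines:

* **Trajectory geometry.** The signed distance of each guest ring's mass
  center from the host center along the cavity axis (wide, secondary-hydroxyl
  rim positive; the rim box spans ±3.95 Å), classified as inside / wide-rim /
  narrow-rim / dissociated; adjacent-unit rim distances
  dO<sub>3-2</sub> = |O3(n) − O2(n+1)| (≤ 3.5 Å permits an intramolecular
  H-bond) and dO<sub>4-4</sub> = |O4(n) − O4(n+1)|; native host–guest
  heavy-atom contacts within 3 Å; guest solvent-accessible surface area
  (Shrake–Rupley).
* **Free-energy surfaces.** Boltzmann inversion of the joint
  (dO<sub>3-2</sub>, dO<sub>4-4</sub>) distribution,
  *F(x,y) = −RT ln P(x,y)*, with rectangular basin occupancies (M1 compact
  H-bonded, M2 glucopyranose rotation, M3 doubly lengthened).
* **MM/GBSA energetics.** A single-trajectory end-point estimator,
  ΔG_bind = ΔE_vdW + ΔE_ele + ΔG_solv,polar + ΔG_solv,non-polar − TΔS,
  with 12-6 Lennard-Jones + Coulomb gas-phase terms, OBC generalized-Born
  polar solvation, γ·SASA non-polar solvation, and TΔS consumed as an input;
  components reported as mean ± SEM over replicates with their additivity
  identities verified.
* **Experimental chain.** Higuchi–Connors phase solubility
  (K_c = slope / (S₀(1 − slope)) for an A_L diagram), Van't Hoff regression
  (ln K_c vs 1/T → ΔH, ΔS; ΔG_exp = ΔH − TΔS), solubility-enhancement folds,
  4PL IC50 fitting and one-way ANOVA with the Newman–Keuls stepdown post hoc
  test.

Because no deposited trajectories or raw assay data exist for such studies,
the `synthetic` module generates every input with recorded ground truth: a
toy 7-unit host plus rigid two-ring guest, Ornstein–Uhlenbeck guest motion
(stable-wide-rim, stable-narrow-rim, dissociating), rim geometry drawn from
configurable Gaussian mixtures, A_L solubility isotherms and 4PL
dose–response curves.

## Worked example

```bash
python examples/04_phase_solubility_thermo.py
```

prints

```
noiseless round trip: Kc = 2245.0 M^-1 (A_L diagram, r2 = 1.0000)
MG/bCD   : dH = -20.77, TdS = -17.06, dG_exp = -3.72 kcal/mol at 30 C
MG/DMbCD : dH = -23.30, TdS = -18.73, dG_exp = -4.57 kcal/mol at 30 C
MG/HPbCD : dH = -17.41, TdS = -13.56, dG_exp = -3.85 kcal/mol at 30 C
MG/bCD   : solubility 11.5 vs 1.7 mg/L -> ~7x
MG/DMbCD : solubility 47.2 vs 1.7 mg/L -> ~28x
MG/HPbCD : solubility 17.1 vs 1.7 mg/L -> ~10x
```

The first line is a generator round-trip: a noiseless A_L isotherm built
with K_c = 2245 M⁻¹ is refit and recovers the truth exactly. The next
three lines push measured stability constants at 30/37/45 °C through the
Van't Hoff chain — negative ΔH means exothermic complexation, and the most
negative ΔG_exp (dimethyl-βCD) marks the most stable complex. The final
lines convert measured solubilities into enhancement folds over the free
guest (1.7 mg/L).

The other examples cover scenario simulation and binding-mode
classification (`01`), rim geometry and free-energy surfaces (`02`),
contacts/SASA/MM-GBSA (`03`) and IC50/ANOVA statistics (`05`). The same
stages are scriptable end-to-end:

```bash
cycloplex run-all --config examples/run_config.yaml --outdir results/demo
```

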