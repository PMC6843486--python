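# Methods

This note records the models, conventions and numerical choices behind
`cycloplex`, and what the synthetic study design does and does not show.

## The toy complex

The host is `n_units` (default 7) pseudo-glucopyranose units placed
symmetrically on a ring. Each unit carries two backbone carbons (C1, C4),
the wide-rim oxygens O2 and O3 at +3.95 Å along the axis, the glycosidic
O4 in the equatorial plane, and the narrow-rim O6 at −3.95 Å. The ±3.95 Å
rim half-height mirrors the ~7.9 Å rim-to-rim span of a natural seven-unit
cyclodextrin; the glycosidic ring radius is set so the symmetric build has
dO<sub>4-4</sub> = 4.5 Å. The guest is a rigid pair of fused hexagons
(bond length 1.4 Å) with its long axis along the cavity axis — an aromatic
A ring on the narrow-rim side and a quinone Q ring (two exocyclic oxygens)
on the wide-rim side, naphthoquinone-like. Per-element radii (C 1.70,
O 1.52 Å), Lennard-Jones parameters (GAFF-scale ε and r_min/2) and small
role-based partial charges are attached; charges are renormalized so each
species carries its declared net charge (default 0) exactly. After
construction both the host and guest mass centers sit at the origin, so a
rigid guest translation of +d Å along the axis reads back as a signed
distance of exactly +d.

`substitution_tag` (none / dimethyl / hydroxypropyl) is carried as a label
only: commercial substituted hosts are mixtures of substitution degrees,
so no fixed-geometry decoration would be representative, and no analysis
here depends on substituent atoms.

## Scenario generator

The guest's axis coordinate follows a discrete Ornstein–Uhlenbeck process
with stationary mean `ou_mean` (Å), relaxation time `ou_relaxation`
(frames) and stationary standard deviation `noise_sigma` (Å):
z_{t+1} = μ + φ(z_t − μ) + σ√(1−φ²)·ε, φ = exp(−1/τ). The stationary
variance is therefore exactly σ² by construction. For the dissociating
scenario the mean ramps linearly to `dissociation_target` (12 Å) over the
first 60 % of frames and holds, carrying the guest past the dissociation
threshold. The threshold defaults to 8 Å — one cavity height beyond the
±3.95 Å rim box — because "dissociated" needs an explicit operational
definition; it is configurable everywhere it is used.

Rim geometry is driven by a per-frame draw of a (dO<sub>3-2</sub>,
dO<sub>4-4</sub>) pair from a scenario-specific Gaussian mixture; all n
unit pairs of a frame carry the same target, placed exactly: the O4 ring
radius realizes the dO<sub>4-4</sub> chord, and dO<sub>3-2</sub> is met
azimuthally while it is within reach of the O3 swing (the O3–O2
intra-unit gap is floored at 30 % of the unit angle to avoid steric
collisions) and by puckering O3 out of the rim plane beyond that — the
out-of-plane motion that lengthens dO<sub>3-2</sub> in real hosts. O6
counter-shifts so the host mass center never moves. Bound-scenario
mixtures sit mostly in the compact H-bonded basin (M1, dO<sub>3-2</sub>
≈ 3.5 ± 0.35 Å, dO<sub>4-4</sub> ≈ 4.5 ± 0.15 Å) with a minority
glucopyranose-rotation component (M2, ≈ 5.0 / 4.85 Å); the dissociating
scenario adds the doubly lengthened component (M3, ≈ 5.0 / 6.0 Å) that
only a guest-free host visits. Default trajectory length is 1800 frames at
0.05 ns/frame (90 ns) in three replicates seeded `seed`, `seed+1`,
`seed+2`; identical seeds give bit-identical output.

What this emulates: occupancy statistics, basin structure, binding-mode
time series, replicate scatter. What it does not: force-field dynamics,
correlated rim/guest motion, solvent, conformational kinetics. Tests that
pass on these data validate the *analysis operators*, not any claim about
real molecular behavior.

## Geometry conventions

* The host axis is the smallest-variance eigenvector of the glycosidic O4
  ring's coordinate covariance, oriented so the O2/O3 centroid side is
  positive (wide rim positive); an explicit flag flips the convention.
  A collinear O4 ring (degenerate second eigenvalue) is an error.
* Binding-mode classification of a window-mean signed distance m:
  |m| ≤ ½·rim_half_height → inside; |m| > dissociation threshold →
  dissociated; otherwise wide_rim / narrow_rim by sign. The band between
  the rim box and the threshold is deliberately attributed to the rims:
  a guest hovering just outside the rim is still rim-associated.
* Native contacts count unique heavy-atom host–guest pairs within 3.0 Å
  via a KD-tree; hydrogens are excluded because 3 Å is a heavy-atom-scale
  cutoff. "Contacts per unit" defaults to total contacts ÷ n_units; a
  per-unit-average mode (`mean_of_units`) is exposed since the two
  conventions differ on asymmetric binding. Means ± SEM always aggregate
  across replicate means with n = number of replicates.
* SASA uses Shrake–Rupley point counting on a deterministic golden-spiral
  lattice (default 960 points, probe 1.4 Å). The guest area is computed in
  the context of the full complex (host atoms occlude); explicit waters do
  not exist in this model and are not emulated. 960 points give < 1 %
  error on an isolated sphere and < 2 % on two-sphere overlaps.

## Free-energy surfaces

F = −RT ln P with the natural logarithm and R = 1.985×10⁻³
kcal·mol⁻¹·K⁻¹ at T = 303 K by default, i.e. RT is the thermal energy per
mole in kcal — the physics convention for Boltzmann inversion. Histograms
use 0.1 Å bins over x ∈ [2, 7], y ∈ [3.5, 7] Å; the surface is shifted so
the occupied minimum is zero and empty bins carry +inf (serialized as the
string "inf"). Basin occupancies are probability masses of rectangular
regions over bin centers, normalized by the full sample count. The default
rectangles are M1: x 2.5–4.5, y 4.1–4.9; M2: x 4.5–5.5, y 4.5–5.2;
M3: x 4.5–5.5, y 5.5–6.5 Å — the approximate basin centers reported for
these coordinates turned into explicit, non-overlapping boxes. Replicates
are pooled before histogramming by default (per-replicate surfaces remain
available by calling per trajectory), since the basins are stationary
properties of the pooled ensemble.

## MM/GBSA estimator

Single-trajectory approximation: host, guest and complex coordinates all
come from the complex trajectory, so for every component
ΔX = X(complex) − X(host) − X(guest), and internal-strain terms cancel —
the gas-phase Δ terms reduce exactly to host–guest cross interactions
(asserted in tests).

* ΔE_vdW: 12-6 Lennard-Jones, Lorentz–Berthelot combination
  (r_min,ij = r_min,i/2 + r_min,j/2, ε_ij = √(ε_i ε_j)), no cutoff.
* ΔE_ele: Coulomb with k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², no cutoff.
* ΔG_solv,polar: canonical pairwise generalized Born,
  −½(1/ε_in − 1/ε_out) k_e Σᵢⱼ qᵢqⱼ/f_GB,
  f_GB = √(r² + αᵢαⱼ exp(−r²/4αᵢαⱼ)), ε_in = 1, ε_out = 78.5. Effective
  radii use the OBC(II) rescaling (α = 1.0, β = 0.8, γ = 4.85) of
  pairwise Hawkins–Cramer–Truhlar descreening integrals with per-element
  screening factors (H 0.85, C 0.72, N 0.79, O 0.85, S 0.80). Two
  deliberate choices: the dielectric offset defaults to 0 Å so an isolated
  atom's effective radius equals its intrinsic radius (exact Born limit);
  and descreening pairs beyond 50 Å contribute nothing (the integral
  decays as d⁻⁴, ~10⁻⁷ per pair at the cutoff), which makes infinitely
  separated species additive to machine precision.
* ΔG_solv,non-polar: γ·SASA + β with γ = 0.0072 kcal·mol⁻¹·Å⁻², β = 0
  (the common surface-tension default), Shrake–Rupley areas at 240 points
  per atom by default inside the estimator (the cheaper lattice changes
  Δ areas by far less than replicate scatter).
* TΔS is an input per system, never estimated: no normal-mode or
  quasi-harmonic machinery exists here, matching the scope of an
  end-point desk estimator.

Snapshots are drawn evenly and deterministically over the trailing window
(default: 300 over the last 20 ns), endpoints inclusive; a window shorter
than the snapshot count is an error, not a silent reuse. Components are
averaged per replicate, then reported as mean ± SEM across replicates.
The ledger identities (ΔE_MM = ΔE_vdW + ΔE_ele; ΔG_solv = polar +
non-polar; ΔG_bind = ΔE_MM + ΔG_solv − TΔS) hold exactly by construction;
`verify_ledger` re-derives them for any ledger — including a transcribed
published table, where the residual tolerance 0.01 kcal/mol corresponds to
two-decimal print rounding (0.005 is the flag default for computed
ledgers).

Absolute component values of published systems are *not* reproducible
here: they require the original force field, trajectories and entropy
method. Only the internal additivity of such tables, and full component
estimates on synthetic systems, are in scope.

## Phase solubility and Van't Hoff

`fit_isotherm` is unweighted OLS of dissolved-guest on host concentration
(no weighting is standard for these diagrams); the diagram is typed A_L
when r² ≥ 0.95 and 0 ≤ slope < 1, and K_c = slope/(S₀(1 − slope)). A
slope ≥ 1 makes the 1:1 formula meaningless and is an error, as is a
non-positive intercept. `vant_hoff` regresses ln K_c on 1/T;
ΔH = −slope·R, ΔS = intercept·R, and TΔS/ΔG_exp are evaluated at a
reporting temperature of 303.15 K. Celsius converts via +273.15
throughout; reference tables quoted at "303 K" are insensitive to the
0.15 K ambiguity at the ±0.05 kcal/mol level. R = 1.985×10⁻³
kcal·mol⁻¹·K⁻¹ everywhere for consistency with the tables this chain
reproduces.

## Assay statistics

The 4PL inhibition model is v(d) = bottom + (top − bottom)/(1 + (d/IC50)^h)
with h > 0, fit by least squares on log dose with a deterministic
multi-start over candidate IC50s (every observed dose plus the mean log
dose); the parameterization makes the fit exactly scale-equivariant
(doses × c ⇒ IC50 × c). Monotonically increasing "viability" is rejected
rather than fit with a negative slope, and fewer than four distinct dose
levels cannot identify four parameters. Viability is assumed
pre-normalized to percent of control. With the standard five-dose design
(1–100 µM) and a low IC50, the upper plateau is weakly constrained and
single-replicate estimates scatter visibly — the reason recovery under
noise is asserted on medians over many replicates, not single fits.

Newman–Keuls: group means are ranked; ranges are tested widest stretch
first against studentized-range critical values q(α, stretch, df_within),
with the harmonic mean of the two compared group sizes under mild
imbalance; every pair inside a non-significant range is declared
non-significant without testing (the stepdown containment rule). Under
the complete null the procedure rejects iff the full-range statistic
exceeds its critical value, so its family-wise error equals α — the
property the 10⁴-simulation test checks. Zero pooled within-group
variance is an error (the statistic is undefined).

## Pipeline and I/O

Trajectories travel as fixed-column multi-model PDB (MODEL/ENDMDL per
frame, chain A host / chain B guest, occupancy 1.00, B-factor 0.00),
read/written through MDAnalysis; coordinates round-trip to the 10⁻³ Å PDB
precision. Charges, radii and LJ parameters cannot ride in PDB columns
losslessly and travel in a sidecar CSV keyed by atom id; the group map is
a JSON sidecar, re-derivable from the naming convention when absent —
missing rim-oxygen labels are reported by unit, never guessed. Units are
Å, kcal/mol and K throughout.

The pipeline demo uses 900-frame (45 ns) replicates, a 100-snapshot
MM/GBSA ledger and strided SASA — problem sizes chosen so a full
`run-all` completes in well under five minutes on one CPU while every
estimator still runs in its standard regime; the acceptance script uses
the full 1800-frame / 300-snapshot design.

## Known limitations

* The toy guest is rigid and moves only along the axis; orientational
  binding modes (guest flipping) are not represented.
* Host rim jitter is perfectly correlated across units within a frame, so
  per-unit-pair statistics are degenerate by design; operators that
  distinguish pairs are tested on hand-built asymmetric cases instead.
* GB screening factors and OBC coefficients are fixed, not refit to any
  particular force field; absolute solvation energies of the toy system
  have no experimental referent.
* The SNK procedure controls family-wise error only under the complete
  null, a known property of the stepdown scheme, and is provided because
  it is the field's customary post hoc test — not as the statistically
  safest choice.
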