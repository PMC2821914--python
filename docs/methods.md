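# Methods

This note records the models implemented in `synucleag`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Gaussian shape model and overlay search

Atoms are isotropic Gaussians `p·exp(−α r²)` with amplitude p = 2.7 and
per-atom exponent `α = π (3p/(4πR³))^{2/3}`, so an isolated atom's integral
equals its hard-sphere van der Waals volume (4/3)πR³ (Bondi radii, 1.7 Å
fallback). Molecular overlap is the first-order (pairwise) sum of Gaussian
product integrals; higher-order intersection corrections are omitted —
the standard fast approximation, adequate for ranking, which slightly
overcounts self-volumes of dense molecules but cancels in the Tanimoto
ratio to first order.

The overlay maximising V_AB is found by gradient-free Powell refinement
over a 7-vector (unnormalised quaternion + translation; the quaternion is
renormalised inside the objective, which leaves a benign gauge direction).
Starts are deterministic: centroid pre-alignment with the identity
rotation, the three axis half-turns, then seeded random unit quaternions
up to `n_starts` (default 10). The reported optimum is never below the
centroid-aligned identity start. Two search budgets exist deliberately:

- single-pair calls (`optimize_overlay`, `shape_tanimoto`): Powell to
  convergence (xtol 1e-4, ftol 1e-8, maxiter 1000) — self-similarity is 1
  to 1e-6 and rigid-motion invariance holds to ~1e-3;
- library screening (`screen_library`): 4 starts, 2 Powell outer
  iterations, loose tolerances (xtol 1e-2, ftol 1e-4). Ranking decoy
  libraries needs score *order*, not converged values; this setting keeps
  a 6-template × 660-molecule screen in the low minutes on one CPU and
  reproduces the ground-truth perturbation order as reliably as the full
  search in our tests.

Optional "colour" (pharmacophore feature) overlap uses the same Gaussian
form over matching feature classes, scaled by a weight w (default 1.0,
radius 1.0 Å). The weight's magnitude is an exposed parameter with no
canonical value; colour similarity is reported separately and never enters
the screening rank.

## Electrostatic Tanimoto

Coulomb potentials (k_e = 332.0636 kcal·Å/(mol·e²)) of both molecules are
evaluated on one shared grid: spacing 0.5 Å, padding 4.0 Å around the
union bounding box, nodes within (vdW radius + 0.5 Å) of any atom of
either molecule masked out. These values trade accuracy for speed (< 1 s
per pair at typical ligand sizes); halving the spacing changes scores in
the third decimal in spot checks. The similarity is
`T_e = ⟨E_A,E_B⟩/(⟨E_A,E_A⟩+⟨E_B,E_B⟩−⟨E_A,E_B⟩)` over unmasked nodes,
algebraically confined to (−1/3, 1]. Both fields identically zero is
signalled as an error (undefined metric). When molecules arrive without
partial charges, Gasteiger (PEOE iterative electronegativity-equalisation)
charges are assigned at read time via RDKit.

## Screening protocol

Per template: rank the whole library by shape Tanimoto, keep the top k1
(default 100); re-rank those by ESP Tanimoto at the shape overlay, keep
the top k2 (default 10). Duplicates across templates are allowed, so 6
templates yield exactly 600 candidates and 60 hits. All ties break
lexicographically by molecule name; all randomness flows from one seed, so
output tables are deterministic.

## Pose contact ranking

Contacts are (ligand heavy atom, region heavy atom or Cα) pairs within a
cutoff, default 4.0 Å — a common literature convention, exposed as a flag.
Ligand hydrogens are excluded by default. Ranking is descending by count
with (conformer id, pose id) tie-break. The count is defined by the brute
force double loop; tests hold any optimised path to exact agreement.

## Trajectory binding analysis

"Bound" means the minimum over all residues' Cα of the distance to the
ligand's mass-weighted heavy-atom centre of mass is strictly below the
cutoff (default 8 Å). The minimum-over-residues reading is the only one
that extends to regions: region occupancy applies the identical rule
restricted to the region's Cα, so the target-region percentage can never
exceed the protein-wide percentage. Occupancies are exact frame fractions;
rounding to integer percent happens only at report time.

Point-charge energies are vacuum Coulomb sums between ligand partial
charges and residue side-chain charge sites — no solvent screening, no
Lennard-Jones, by design qualitative. Means and sample (n−1) standard
deviations are taken over **all** frames by default (a `bound_only` option
restricts to bound frames); frames are weighted equally regardless of
timestep. Normalisation divides every mean by |reference| where the
reference is the most negative mean among neutral ligands (integer net
charge 0), mapping that row to −1.0; charged-ligand rows may exceed
magnitude 1. A table with no negative neutral mean has no defined
normalisation and raises.

Hydrogen bonds use donor–acceptor ≤ 3.5 Å plus a D–H···A angle ≥ 120°
when explicit hydrogens exist, falling back to the heavy-atom distance
rule otherwise; hydrophobic contacts are ligand-carbon / side-chain-carbon
pairs < 4.0 Å. All geometric thresholds are exposed parameters.
Persistence (per residue and contact kind) is the fraction of frames with
at least one event, flagged when strictly above 0.5.

## ThT kinetics

The logistic `F0 + A/(1+exp(−k(t−t50)))` is the standard empirical
sigmoid for nucleated polymerisation curves; it is fitted per replicate by
Levenberg–Marquardt least squares with quantile-based initialisation
(F0 = 5th percentile, plateau = 95th, t50 = first half-rise time, k from
the maximum finite-difference slope via max-slope = Ak/4). Convergence is
reported honestly via a flag (positive A and k, finite residuals, RMSE
below half the data span, t50 within an expanded time window) — degenerate
flat curves flag rather than raise. The lag is the tangent-intercept
`t50 − 2/k`. Replicates are fitted individually and lags averaged per
sample, preserving replicate variance for the one-way fixed-effects F-test
(α = 0.05 default); groups with fewer than two replicates are excluded
with a warning. With exactly identical groups the F statistic is 0 and
p = 1. The F-test is a documented choice for an otherwise unspecified
group comparison; it is not a mechanistic model, and mechanistic
nucleation–elongation fits are out of scope.

## Fibril morphometry

Length classes: short < 0.5 µm, intermediate 0.5–0.75 µm inclusive,
mature > 0.75 µm. Assigning the boundary lengths to the intermediate class
is forced by the strict outer inequalities; the two thresholds are
parameters. Spherical/oligomeric structures are never length-classified
and pass through flagged. Width statistics are mean ± sample sd over
measurements that carry a width. Dominant-class ties resolve toward the
longer class.

## Synthetic generators: what they emulate, what they do not

Every generator is a pure function of (inputs, seed) and stores its ground
truth in output metadata, so each analysis stage can be scored without
re-derivation.

- **Ligand library**: each template spawns decoys whose coordinates are
  displaced by zero-mean Gaussians with sd = i·perturb_sd for decoy i
  (default step 0.15 Å) and charges jittered with relative sd 0.02·i. The
  linear growth gives a unique ground-truth similarity order for
  monotonicity tests. A single realisation of a larger perturbation can
  occasionally look more template-like than a smaller one, so order
  recovery is asserted statistically (pairwise concordance over seeds),
  not per-seed. The six built-in templates are procedural dopamine-like
  shapes (catechol/quinone/indole motifs), not real chemistry: one is a
  +1-charged ammonium analogue; the others are integer-neutral with a
  small positive excess on the amine tail, as catecholamines carry at
  physiological pH.
- **Protein conformer**: a persistent self-avoiding random walk with
  3.8 ± 0.1 Å Cα steps and non-bonded pairs kept above 3.5 Å, annotated
  NAC 61–95 / target 125–129, with −1 e side-chain sites (plus
  carboxylate-like oxygens) at E61/E83 and a Cβ-like carbon per residue.
  It has realistic local geometry but no secondary structure, ensemble
  thermodynamics, or NMR-derived restraints.
- **Trajectories**: bound frames place the ligand COM uniformly in
  [2 Å, cutoff − 0.5 Å] from a randomly chosen Cα (optionally within one
  region); unbound frames sit beyond 2 × cutoff from every Cα. The margin
  construction makes the 8 Å criterion unambiguous, so occupancy recovery
  is exact by design — passing says the classifier implements the rule
  correctly, not that real MD occupancies would be error-free.
- **ThT curves**: the true logistic plus i.i.d. Gaussian noise on a
  5-minute grid over 0–100 h (1201 points); defaults F0 = 10, A = 100,
  t50 = 40 h, k = 0.2 h⁻¹ (lag 30 h), noise sd = 2 (2% of amplitude) —
  a mid-assay lag with a clean plateau inside the 100 h window. Real
  plates add drifts, evaporation and replicate heterogeneity that the
  generator does not model.
- **Fibril populations**: class labels from a categorical mix (default
  0.2/0.3/0.5 short/intermediate/mature), lengths uniform strictly inside
  each class range with a ±0.01 µm margin at the 0.5/0.75 µm boundaries
  (so label recovery must be 100%), widths Normal(9.2, 2.2) nm truncated
  at 1 nm, matching TEM-scale width statistics.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use a 660-molecule screening
library (6 templates × 110), 1000-frame trajectories for occupancy, 50
random frames for contact-detector oracles, 100 simulated curves for
kinetics recovery, and 107–1000-fibril populations — sizes at which every
stage's behaviour is already asymptotically stable while a full run stays
in the low minutes on a single CPU.

## Known limitations

- The point-charge energy scale is qualitative by construction; no
  force-field terms beyond Coulomb, no solvent.
- The overlay search is local multi-start; pathological shapes could in
  principle trap all starts, though the identity-start guarantee bounds
  the damage for near-aligned inputs.
- MOL2/PDB small-molecule reading accepts one molecule per file; SDF is
  the multi-molecule interchange format (and the only one that round-trips
  partial charges exactly, via an atom property list).
- Pose generation, MD itself, NMR ensemble clustering and raw AFM/TEM
  image segmentation are out of scope: poses, trajectories and measurement
  tables are consumed, not produced.
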