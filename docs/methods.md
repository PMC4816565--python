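# Methods

This note documents the models implemented in solvshell, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the package's numerical conventions.

## Two-state unfolding thermodynamics

Unfolding is treated as a reversible two-state equilibrium N ↔ D with no
populated intermediates. The observed fluorescence intensity at a fixed
emission wavelength is a population-weighted mixture of the native and
denatured baselines, taken as *fixed anchors* F_N (native protein in
water) and F_D (fully denatured reference condition), not as fitted
sloping baselines. The equilibrium constant and free energy at any
observed intensity are

    K = (F_obs − F_N) / (F_D − F_obs),    ΔG_D = −RT ln K,

with R = 8.314 J mol⁻¹ K⁻¹ and T defaulting to 313 K (titrations and
simulations of this system are run at 40 °C; the temperature is
configurable per curve). ΔG_D is fitted against denaturant
concentration c (% v/v) by ordinary least squares — the linear
extrapolation model — giving the m-value (−slope) and the water-limit
stability ΔG° (intercept). Weighted fits are available but not the
default; regression diagnostics (R², slope standard error) are
reported.

Points with F_obs outside the open (F_N, F_D) interval carry no
two-state information (K would be negative or infinite); they are
excluded from fits with a warning rather than clamped. Anchors may be
given in either order — a signal that decreases on unfolding works
identically — and swapping them flips the sign of every ΔG_D.

**Known statistical behaviour.** ln K diverges as F_obs approaches
either anchor, so titration points within ~2 noise SDs of an anchor
contribute strongly biased free energies. The synthetic curve
generator therefore defaults to a *well-conditioned* design: ΔG° = 5
kJ/mol and m = 0.25 kJ/mol per % v/v on a 0–40 % grid (n = 9), which
puts the transition midpoint at 20 % and keeps both end points ≥ 5
noise SDs (at SD 5 on a 200-unit span) away from the anchors. Under
these conditions the unweighted estimator recovers ΔG° without
detectable bias in Monte-Carlo replication. Ill-conditioned designs
(baseline points hugging an anchor) visibly bias the intercept upward;
users analysing real titrations should either discard anchor-adjacent
points or use the optional inverse-variance weights.

Residual enzymatic activity is reported as a percentage of the control
condition (100 · units/control-units), with one unit defined by the
standard titrimetric convention (1 µmol NaOH equivalent per minute).

## Structure and trajectory handling

PDB input (ATOM/HETATM, MODEL/ENDMDL, CRYST1, REMARK 2, TER, END) is
parsed and written through gemmi; the first model of a multi-model file
is the structure, the model count and any REMARK 2 resolution are kept
as metadata, and CRYST1 becomes an orthorhombic periodic box. XYZ
trajectories use the conventional count/comment/atom-lines layout with
an optional `t= <ps>` stamp in the comment; frames without stamps get
0, 1, 2, … ps. All coordinates are Å internally (PDB native);
reporting utilities convert to nm where that is the field's
conventional unit (Rg, RMSF). Residue numbering follows the file —
no renumbering — because residues are cited by their crystallographic
numbers.

Species classification maps residue names to {protein, water, DMF,
trehalose, ion} (defaults cover HOH/SOL/WAT, DMF, TRE/TRH and the
standard amino acids; a CSV can override) and flags the counted role
atoms: the water oxygen; one carbon per DMF molecule — the formyl
carbon, identified as the carbon bonded to the molecule's oxygen, with
an "all carbons" mode available since the choice of one vs three
counted carbons is a convention; and the 8 hydroxyl oxygens of
trehalose (O2/O3/O4/O6 on each glucopyranose ring by naming convention;
ring O5 and the glycosidic oxygen are excluded). One counted atom per
water and per DMF keeps the three species' local densities comparable.

## Conformational metrics

Superposition is the weighted least-squares proper rigid-body fit
(Kabsch); reflections are never admitted, and degenerate (collinear or
< 3-point) selections are rejected. The Cα-RMSD series is computed
against frame 0 with unit weights; Rg is mass-weighted with element
masses. RMSF uses the standard single-iteration scheme: frames in the
analysis window are superposed on the first window frame, averaged,
re-superposed once on that mean, and fluctuations are measured about
the final mean. "Total RMSF" is the *sum* over residues (a single
flexibility score that preserves the conventional presentation), in nm.

Metrics do not unwrap periodic images; trajectories must contain whole
molecules (the synthetic generator guarantees this, and typical
post-processed MD trajectories satisfy it). Analysis windows default
to the final 60 % of frames, the usual "equilibrated tail" choice for
10 ns production runs analysed over their last 6 ns.

## Solvation-shell statistics

Two complementary geometries are used, because they answer different
questions:

* **RDF from the centre of mass** — per frame, the minimum-image
  distance of every role atom from the protein COM is histogrammed,
  normalised by spherical-shell volume and the role's bulk number
  density, and averaged over the analysis window. This is the global
  "how far out does each species sit" picture.
* **g_NOW over minimum-distance shells** — per frame, each role atom
  is assigned to the 0.5 Å band (r_lo, r_hi] containing its minimum
  distance to any protein *heavy* atom (hydrogens excluded, matching
  united-atom practice); band counts are time-averaged *before* the
  ratio is formed, so sparsely occupied bands aggregate information
  across frames instead of producing wild per-frame ratios. Shells
  with zero total count are reported as missing (NaN), never as zero,
  so >1 / <1 comparisons stay meaningful. A cumulative-shell variant
  (count everything within r_hi) is available behind a flag.

All distances use the minimum-image convention in orthorhombic boxes
only; RDF bins beyond half the smallest box edge are rejected. Periodic
neighbour searches go through a toroidal k-d tree; brute-force oracles
in the test suite confirm exact agreement.

## Hydrogen bonds

The geometric criterion is donor–acceptor distance ≤ 3.5 Å and
H–donor–acceptor angle ≤ 30°, the de facto standard. When the input
has no hydrogens (crystal structures, reduced synthetic systems),
donors fall back to a heavy-atom list per residue template and the
angle test is skipped. Donor–acceptor pairs that are covalently 1-2 or
1-3 bonded are excluded (bonds inferred from distance: < 1.8 Å
heavy–heavy, < 1.25 Å to H). DMF has no conventional donor hydrogens;
an opt-in weak-donor flag admits C–H donors for users who want to score
methyl-donor contacts, but it is off by default to keep the criterion
chemically conventional.

Censuses classify each bond by the species pair of its partners
(protein labelled CRL): CRL-CRL, CRL-DMF, CRL-Tre, DMF-Tre, other.
Summaries are means ± population SD over frames, so a single frame has
SD 0 by construction.

The per-bond energy estimator is an explicit empirical well,

    E(d, θ) = E₀ · (5(d₀/d)¹² − 6(d₀/d)¹⁰) · cos²θ,
    d₀ = 2.8 Å, E₀ = 28 kJ/mol,

reported as a positive magnitude. It is a documented, swappable
reproduction aid that puts bond strengths on the conventional tens-of-
kJ/mol scale — *not* a force-field energy. Being a 12-10 well it peaks
at d₀ and decays monotonically beyond it; at distances below d₀ the
magnitude drops again (steric wall), and distances outside [2.0, 4.5]
Å trigger an out-of-calibration warning.

## The synthetic-data generator

The generator provides *statistical* ground truth, not physics: no
force field, no solvent–solvent excluded volume, no equilibration.

* **Toy proteins** are poly-alanine backbones (N, CA, C, O per residue)
  on ideal helix (1.5 Å rise, 100°/residue, 2.3 Å Cα radius) or
  extended (3.5 Å/residue) geometry — enough structure for
  superposition, Rg/RMSF and donor/acceptor assignment.
* **Solvated boxes** place role atoms by inhomogeneous Poisson
  sampling: bulk density × a piecewise enrichment factor e_s inside a
  near-protein shell (default 4 Å of minimum distance), with a hard
  2 Å exclusion radius. Realised per-region counts are asserted to lie
  within 4 Poisson SDs of expectation at generation time. Water and
  DMF are single role atoms; trehalose is an 8-oxygen rigid template
  (two staggered rings, ~1.8 Å radius) whose *centre* follows the
  enrichment profile — template atoms may therefore leak ~1.8 Å past
  profile boundaries, a documented geometric blur. Default
  composition: water at its pure-liquid oxygen density 0.0334 Å⁻³,
  DMF 2 mol/L, trehalose 0.5 mol/L, in a 60 Å cube.
* **Trajectories** offer four motion models: static; rigid (random
  proper rotation + translation per frame — superposed metrics must
  read zero); jitter (i.i.d. Gaussian per coordinate, default σ 0.5 Å;
  solvated-box presets use σ = 1.0 Å, a deliberate decorrelation scale
  for snapshots meant to be hundreds of ps apart); and drift (uniform
  scaling about the centroid, giving exactly proportional Rg growth).
  For solvation statistics there is additionally a *resampling* mode
  that re-draws all solvent positions from the planted profile each
  frame — the diffusive limit in which snapshots are fully
  decorrelated. Jittered frames leave each molecule near its base
  position, so frame-averaging cannot remove configuration noise from
  clustered species (one trehalose contributes 8 correlated oxygens);
  resampled frames can, and the null-calibration tests use them.
* **Hydrogen-bond fixtures** plant exact per-class donor–H–acceptor
  triples at (2.8 Å, 10°) on a well-separated grid, plus decoys that
  violate distance (4.0 Å) or angle (60°); the census must recover the
  planted counts exactly.
* **Fluorescence curves** are generated from the forward two-state
  model with Gaussian intensity noise; noise-free curves invert exactly
  (closed-form round trip) and noisy ensembles recover the planted ΔG°
  within Monte-Carlo error under the well-conditioned default design
  described above.

What passing tests on synthetic data do *not* show: real solvent
structure (layering, orientational correlations), force-field accuracy,
finite-sampling artefacts of actual MD, or fluorescence baseline drift.
They show that the *analyses* are correct: every statistic recovers
what was planted, agrees with brute-force enumeration, and respects its
invariances (rigid motion, solvent duplication, species permutation).

## Pipeline and reproducibility

The config-driven runner validates all inputs before computing
anything, streams one analysis at a time, and writes one TSV per
analysis plus a JSON manifest (package version, seed, parameters, input
SHA-256 checksums, output paths). All randomness flows from the single
seed in the config; re-running with the same config yields
byte-identical TSVs. Exit codes: 0 success, 2 validation failure,
3 computation failure.

Problem sizes used throughout the shipped configurations — a
20-residue helix in a 60 Å box (~8,000 atoms), 20 frames, 100
Monte-Carlo titration replicates — were chosen as the smallest systems
in which every planted effect is statistically unambiguous.

## Known limitations

* Orthorhombic boxes only; no triclinic cells, no trajectory
  unwrapping.
* PDB subset: altlocs and insertion codes pass through untouched;
  mmCIF and compressed trajectory formats are not read.
* The hydrogen-bond energy estimator is heuristic (see above).
* The linear-extrapolation fit assumes two-state behaviour; three-state
  or kinetic analyses are out of scope.
* Minimum-distance shells use protein heavy atoms; with explicit
  protein hydrogens present, contact distances shift ~1 Å shorter than
  the united-atom convention this package adopts.
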