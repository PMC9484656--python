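# Methods

## The comparison problem

The package compares two conditions of a multi-domain protein sampled
as replicated MD trajectories. The target system is ATP7B-like: a
catalytic core (M, A, P, N domains) plus a regulatory N-terminal tail
(N-terminal peptide, MBD1–6, linkers), 17 named segments over residues
5–1378 in the default map. Three families of observables are compared:
domain–domain center-of-mass distances, per-axis domain positions in a
core-fixed frame, and residue–residue contact frequencies.

All lengths are nm and times ps internally (structure formats in Å are
converted on read); free energies are in $k_BT$ at the recorded
temperature (default 303.15 K, a typical simulation temperature for
this system).

## Statistical model

Frames within a trajectory are strongly autocorrelated, so frame counts
wildly overstate the information content of a trajectory. The package
therefore treats the *replica trajectory* as the unit of independence:
each trajectory is reduced to its time-average of the observable, and
the two groups of replica means (typically 6 replicas × 2 runs = 12 per
condition) enter an independent two-sample t-test. The test is gated on
Levene's test for equal variances at the same α: if Levene's p ≥ α the
pooled-variance t-test is used, otherwise Welch's test. The gate's
failure branch is a genuine design choice (falling back to Welch is the
conservative standard); both the branch taken and the Levene p are
recorded in every output row. Levene's test uses the median-centred
(Brown–Forsythe) variant by default, configurable to mean-centred.

No multiple-testing correction is applied by default — the convention
for this analysis is raw per-pair p < 0.05 across the 45 domain pairs —
but a Benjamini–Hochberg helper is provided for reporting alongside.

Tests are two-sided throughout. Cross-correlations between MBD axis
positions and tail radii of gyration are Pearson r over all replica
averages of both conditions pooled (24 points in the default layout),
with cells masked at p < α.

The Monte-Carlo diagnostics in `domaindyn.validation` justify this
design: with AR(1) frame autocorrelation φ = 0.8 and no condition
difference, the replica-mean test rejects at its nominal 5% rate
(a frame-level test would reject at many times that), and an injected
1 nm mean shift at σ = 0.2 nm within-replica spread is detected with
power ≈ 1 and estimated without detectable bias.

## Geometry

- COM, Rg and RMSD are mass-weighted (the common default in MD
  toolchains; geometric weighting is available by passing unit masses).
- Superposition is weighted Kabsch (SVD with reflection guard) on a fit
  selection, applied rigidly to all atoms. The default alignment
  selection is the M+P domain block, which fixes x/y as the membrane
  plane and z as its normal in the reference structure. Loop regions
  can be excluded from fit/measure selections via per-call exclusion
  intervals; no loops are excluded by default because there is no
  canonical enumeration of them.
- Free-energy surfaces use F = −ln(n/n_max) over a 2D histogram, 50×50
  bins by default over the observed range padded 2% per side. Occupied
  bins renormalize exactly back to the empirical histogram; unoccupied
  bins are +inf, never 0. Combining runs pools frames with equal
  weight before histogramming.
- Equilibration detection fits RMSD(t) = a·ln(t + t₀) + b with t₀ fixed
  at one frame interval (avoiding ln 0), and declares equilibration at
  the earliest time where the fitted derivative a/(t+t₀) drops below a
  threshold, default 0.005 nm/ns (i.e. < 0.05 nm drift per 10 ns).
  The threshold is a reporting convention, not a physical constant.

## Contacts

A contact is any heavy-atom pair from residues of *different* segments
within 0.45 nm (strict `<`); the Cβ–Cβ starting-structure reference map
uses ≤ 0.8 nm with Cα fallback for residues lacking Cβ. Same-segment
pairs (both residues in one domain or one linker) are excluded by
construction and stored as NA. Heavy atoms are judged by the element
field, falling back to the atom name's first alphabetic character.

Frequencies pool all frames of a condition with equal weight (a
per-replica mode exists for uncertainty estimates). The >5% threshold
is applied only for rendering; difference maps always subtract raw
frequencies, with a pair missing from one condition counted as 0 there.
Per-residue interface profiles aggregate over partners by maximum
(default) or sum.

Neighbor search uses a KD-tree range query over the eligible atoms —
the same O(N) pruning a cell grid at cutoff-sized cells provides — and
its exact equality with a brute-force all-pairs scan is enforced by
randomized oracle tests at both working cutoffs.

## Copper centers

Each CXXC motif is patched into a linear bi-coordinated Cu(I) center:
thiol hydrogens are stripped, a Cu pseudo-atom is added midway between
the SG atoms, S and Cu partial charges come from a parameter block, and
the residual charge is spread uniformly over *all remaining atoms of
the two cysteinates* (the literal reading of "all atoms except S and
Cu", backbone included) so the center totals exactly −1 e. Proportional
spreading is available as an option. The shipped S/Cu charges are
placeholders for pipeline testing, not force-field values; production
use requires a user-supplied parameter config. Geometry validation
reports per-frame Cu–S distances and the S–Cu–S angle, flagging centers
whose mean angle strays more than 30° from linear.

## Synthetic ensembles

The generator emulates the statistical structure the pipeline must
resolve, not the physics:

- each domain is a rigid residue lattice riding an AR(1)
  center-of-mass track, x_t = φx_{t−1} + √(1−φ²)·σ·ε, initialized
  stationary so the marginal spread is σ and lag-1 autocorrelation φ
  (default σ = 0.2 nm, φ = 0.8 — strong enough autocorrelation to break
  any frame-level test);
- linker residues interpolate between flanking domain tracks with
  0.1 nm jitter;
- condition effects: per-domain mean offsets, a radial tail-anchor
  scale (holo default 1.25, producing the compact ≈4.1 nm vs extended
  ≈5.6 nm tail-Rg regimes in the fixture), and per-pair contact
  propensity overrides realized by Bernoulli placement of one residue
  within 0.35 nm of its partner;
- layout: 2 conditions × 2 runs × 6 replicas × 200 frames at 100 ps by
  default, mirroring the 12-trajectories-per-condition replica-exchange
  design the statistics are built for;
- three pseudo-atoms per residue (CA/CB carbon + one hydrogen) so the
  heavy-atom filter and Cβ maps are exercised; masses uniform.

The default fixture is a 1/7-scale ATP7B-like map (same 17 segment
names, discontinuous M and P domains preserved, ~200 residues, ~600
atoms). Everything derives from one integer seed: regeneration is
bit-identical, including the written PDB/XTC files.

What the generator does *not* emulate — excluded volume, realistic
secondary structure, domain rotation, force-field energetics, solvent
and membrane — bounds what passing tests show: they validate the
*measurement and inference machinery* (geometry arithmetic, contact
counting, calibration and power of the statistics) on data with the
right correlation structure, not the biophysics of any real system.

## Problem sizes

Deskside defaults keep every stage fast: fixtures of ~600 atoms and
100–200 frames per trajectory, 2,000 Monte-Carlo repetitions for the
null-calibration diagnostic and 300 for power estimation. These sizes
give binomial CIs tight enough to detect miscalibration of a few
percentage points; all are parameters, so larger studies simply pass
larger numbers.

## Numerical conventions and degenerate inputs

- Cutoff comparisons: strict `<` for the 0.45 nm contact map, `≤` for
  the Cβ reference map; the 5% threshold is strict `>` (a pair present
  in exactly 1 of 20 frames is dropped).
- Kabsch superposition rejects fit selections with < 3 atoms or
  rank-deficient (collinear/coincident) reference geometry.
- Identical constant groups in `compare` return t = 0, p = 1 rather
  than 0/0.
- Empty selections raise immediately (they almost always mean a
  residue-numbering mismatch between map and topology).
- Arccos arguments are clipped to [−1, 1] before angle evaluation.

## Known limitations

- Periodic-boundary unwrapping is not performed on read; trajectories
  are assumed whole-molecule (true of the generator's output and of
  typical post-processed production trajectories).
- The per-replica contact mode recomputes the full map per member;
  for very large residue counts a sparse accumulation would be needed.
- The axis-position analysis is only as meaningful as the shared
  reference frame; it uses one reference structure for both conditions
  (first apo replica by default) aligned on M+P.
- Replica-exchange demultiplexing is out of scope: each replica file is
  treated as one continuous trajectory, as in the intended use.
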