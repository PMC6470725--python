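# Methods

This note documents the models implemented in `ctxtraj`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Units, numbering and preprocessing

Coordinates are nm, times ns, energies kJ/mol — except the Kabsch–Sander
hydrogen-bond energy, which is kept in kcal/mol with its conventional
−0.5 kcal/mol bond threshold.  Residue numbering is 1-based author
numbering.  Trajectories are preprocessed by discarding an equilibration
segment (frames with `t ≤ discard`, 200 ns for the original study setup)
and subsampling at a stride that must be an integer multiple of the native
spacing (0.1 ns sampling in the study conditions).  The package assumes
whole, unwrapped molecules: if a periodic box is present and a peptide bond
exceeds 0.25 nm, loading fails with a "broken molecule" error rather than
attempting re-imaging, which is out of scope.  Solvent atoms are retained
only for the solvation operations and ignored everywhere else.

## Secondary structure

Hydrogen bonds are scored with the Kabsch–Sander electrostatic model,
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with distances
in Å, bond when `E < −0.5`.  Assignment follows the classical pattern
rules: n-turns (n = 3, 4, 5) yield G/H/I helices when two consecutive turns
overlap; bridge patterns yield B (isolated) or E (ladders of ≥ 2
consecutive bridges); remaining turn interiors are T; Cα kinks above 70°
are bends S; priority H > E > B > G > I > T > S > C.  Bridges require both
partners to have sequence neighbors, so chain-terminal residues are never
E/B — as in the original algorithm.  Amide hydrogens must be present in the
input and are never rebuilt; prolines and chain-start residues (free
N-terminal amine, not an amide) carry no H and simply cannot donate.

The 8 labels reduce to the three reported classes plus coil as
H → α-helix; E, B → β-sheet; T, S → β-turn/bend; G, I, C → coil.  Pooling
G/I with coil reflects their rarity; the map is a constructor argument, so
either reading of "β-turn/bend" (or counting 3₁₀ toward helix) is a
one-line override.

## Superposition, RMSD, RMSF

Superposition uses the Kabsch SVD solution with the determinant correction,
so reflections are never returned.  Weights are uniform (Cα-trace
convention); mass weighting is available but off by default.  RMSF is
computed after superposing every frame on a reference — the iterative
self-average by default, or external coordinates to measure fluctuation
about another peptide's average (analog-to-reference comparisons use
positional residue correspondence, valid because the substitutions are
isosteric).  The iterative mean alternates {superpose all frames on the
current mean; re-average} until the mean moves < 1e-6 nm RMS.

Superposition removes six rigid-body degrees of freedom, so an isotropic
ensemble's RMSF is reduced by the factor √(1 − 6/(3n)); fixtures validating
the σ√3 closed form use n = 200 atoms, which keeps that bias below 0.5 %.

## Contacts, H-bonds, CβHβ statistic

Residue–residue contacts are frame fractions in which the minimum
heavy-atom distance within the requested role is ≤ 0.5 nm; the backbone set
is {N, Cα, C, O}, the sidechain set is every other heavy atom.  Residues
without sidechain heavy atoms (Gly) are flagged missing, not reported as
zero.  H-bonds use the geometric criterion d(D,A) ≤ 0.35 nm and deviation
from donor–H–acceptor linearity ≤ 30°, the convention of the analysis
utility this reproduces; donors are N/O atoms with an attached hydrogen
(resolved by proximity in the first frame, since topologies carry no bond
list).  The disulfide surrogate statistic is the distance between the
mass-weighted centers of {Cβ, Hβ1, Hβ2} of a residue pair (C 12.011,
H 1.008), reported as mean ± SD with the contact probability at the
one-sided 95 % reference threshold of 0.26 nm; `ci95_threshold` computes
that percentile from any user-supplied reference distance series.

## SASA, rSASA and hydration

SASA is Shrake–Rupley with a deterministic golden-spiral mesh (1000
points/sphere, probe 0.14 nm) over heavy atoms with Lee–Richards-style
radii (C 0.170, N 0.155, O 0.152, S 0.180 nm; user-overridable).  rSASA
divides residue SASA by the residue type's maximum SASA from reference
tripeptide ensembles (Cys 0.758, Ser 1.219, Abu 1.347 nm²); values above 1
are legitimate and returned unclipped.

Hydration uses single-site water oxygens.  `rdf` is the standard g(r)
normalized by the bulk density derived from the box volume and water count.
`shell_probability` reports, by default, the mean water count within the
0.5 nm shell divided by the bulk-density expectation for the same volume —
a dimensionless occupancy that equals 1 in bulk and equals the integral of
g(r) over the shell.  Because the normalization of a "probability of
finding water" is not uniquely determined by its reported values, the raw
mean count is retained as an explicitly labeled second mode rather than
guessing a single intent.

## Dihedral PCA and free-energy landscapes

φ = (C₋₁, N, Cα, C) and ψ = (N, Cα, C, N₊₁) torsions (IUPAC sign) are
encoded per residue as [cos φ, sin φ, cos ψ, sin ψ], which removes angular
periodicity: rotating all angles by a constant offset is an orthogonal
transformation of the encoded data, so the PCA spectrum is invariant.  PCA
is an eigendecomposition of the covariance, deterministic up to column
sign, which is fixed by making each eigenvector's largest-magnitude loading
positive.

The landscape is `ΔG = −R·T·ln(ρ/ρ_max)` on a 2-D histogram of the first
two components (default 100×100 bins over the bounding box expanded 1 %,
T = 310 K, R = 8.3145 J/mol/K).  Empty bins are masked, never assigned a
finite energy; the maximally occupied bin is exactly 0.  Basins are
8-connected components of occupied bins that contain at least 2 bins and
descend below 5 kJ/mol (~2 RT at 310 K) — small enough to exclude stray
single-frame bins, large enough to keep metastable minima; because empty
bins never connect components, basins separated by unsampled space are
always distinct.  Basin free energies integrate occupancy over the whole
component (`−RT·ln(N_b/N_max)`), which is much better conditioned than the
single-bin minimum; representative conformers are still the frames in each
basin's minimum-ΔG bin nearest the bin center, ordered by that minimum.

Basin identification uses k-means (scikit-learn, k-means++-style
initialization, 50 restarts, fixed seed) over candidate k with SSE and
average-silhouette-width diagnostics; the default selection maximizes the
silhouette, replacing visual inspection with a documented criterion while
leaving k a manual override.  Silhouettes are evaluated on a seeded 5000-
frame subsample when ensembles are larger (the full pairwise matrix scales
quadratically).

## Essential subspaces, RMSIP and nRMSIP

The essential basis is the eigenbasis of the covariance of superposed Cα
coordinates (uniform weights, frames superposed on the iterative mean).
RMSIP over the first N eigenvectors of two bases, and its normalized form
dividing by the geometric mean of each trajectory's half-vs-half
self-consistency (halves split by frame count, each superposed on its own
mean), are implemented exactly as defined; nRMSIP can exceed 1 when
cross-overlap beats self-consistency and is flagged rather than clipped.
Values ≥ 0.65 are reported in four classes ([0.65, 0.75), [0.75, 0.85),
[0.85, 0.95), [0.95, ∞)).

N is a required report parameter (default 10, printed in all outputs).  N
should not exceed the effectively sampled essential dimension: eigenvectors
beyond it are sampling noise, and with rank-3 test ensembles the statistic
at N = 10 mostly measures noise self-consistency, so the recovery tests use
N = 3 to match the generative rank.

## Synthetic generators

The generators produce the statistical structures the analyses assume, with
exact ground truth:

* **Markov–von Mises dihedrals** — a hidden Markov chain over K
  conformational states with per-residue von Mises φ/ψ emissions.  Default
  test conditions: two states (helix-like (−57°, −47°) vs strand-like
  (−139°, 135°)), κ = 50 (angular SD ≈ 8°, a realistic basin width), 3:1
  stationary odds with mean dwell times of 20 and ~7 frames — clearly
  metastable yet fast-mixing enough that 20 000-frame occupancies resolve
  the stationary distribution to about one percentage point.
* **NeRF chain rebuilding** — poly-Ala-like backbones (ideal bond lengths
  and angles, ω = 180°) with optional Cβ/Hβ pseudo-atoms and Cys/Abu/Ser γ
  atoms, so dihedral ground truth also exists in Cartesian form; extracting
  torsions from a rebuilt chain reproduces the inputs to ~1e-15 rad.
  Sidechain rotamers are not modeled.
* **Gaussian fluctuation ensembles** — frames ~ N(reference, Σ) with Σ
  isotropic, per-atom 3×3, or low-rank over orthonormal displacement modes;
  `low_rank_modes` projects out rigid-body translations/rotations so the
  prescribed modes survive superposition.
* **Solvation scenes** — single-site waters at a bulk number density
  (default 33 nm⁻³, ambient water) with per-tagged-atom shell density
  multipliers.  The fixed per-frame water count is apportioned between bulk
  and shells by a multinomial with volume×multiplier weights, so shell
  occupancies follow the prescribed local density at constant atom count.
* **Ideal geometries** — an α-helix at (−57°, −47°) and a flat antiparallel
  two-strand sheet built by a deterministic grid search over strand
  separation and registry that maximizes Kabsch–Sander bonds subject to a
  0.17 nm steric floor.

All generators draw from one explicitly seeded `numpy.random.Generator`
and are bit-reproducible.  They emulate the statistical structure of
conformational ensembles, not their physics: no excluded volume between
residues, no solvent structure beyond density control, no correlated
dihedral dynamics within a state.  Passing tests therefore demonstrate that
the analysis layer recovers known statistical ground truth, not that it
reproduces any particular peptide's measured values — the study's absolute
numbers derive from microsecond all-atom MD and are out of reach of desk-
scale synthetic data by design.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen so sampling error sits well
inside each stated tolerance: 20 000 frames for occupancy/subspace
recovery, 50 000 × 200 atoms for the RMSF closed form, 40×40 FEL grids for
two-basin landscapes (peak bins hold hundreds of counts), 300-frame
solvation scenes, 200 Monte-Carlo draws for the √(N/d) RMSIP expectation.
Degenerate inputs fail loudly: fewer than 3 or collinear points in Kabsch,
empty selections, missing backbone atoms or amide hydrogens (named in the
error), non-stochastic transition matrices, non-PSD covariances, shells
that do not fit the box.

## Known limitations

* DSSP reduction pools G/I with coil; structures rich in 3₁₀-helix will
  read as less helical than the full 8-label trace shows.
* H-bond donor detection is proximity-based (no bond topology); unusual
  protonation states may be missed.
* PDB numbering is positional (1..n per chain), matching the rebuilt
  fixtures; author insertion codes are not preserved.
* The FEL is a histogram estimate — no reweighting or kernel smoothing —
  and basin statistics inherit histogram noise in sparsely sampled regions.
* `nrmsip` assumes stationarity within each trajectory; drifting ensembles
  deflate the self-consistency denominator and inflate the ratio.
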