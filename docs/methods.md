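# Methods

This note documents the models, conventions and numerical choices behind
`loopdyn`, and what validation on synthetic ensembles does and does not
establish.

## Data model

A `Topology` holds atoms (PDB-convention names, elements), residues grouped
by (chain, resSeq) and re-indexed 0-based and contiguous (author numbering is
kept as metadata only), purine/pyrimidine typing from the residue name
(A, G purine; C, U pyrimidine; anything else "unknown" and excluded from χ
analysis), and a list of symmetry permutations that always contains the
identity. `set_symmetry` adds the strand-swap permutation of a
self-complementary duplex after verifying that the two chains have identical
residue sequences and per-residue atom-name multisets; the permutation is an
involution by construction. A `Trajectory` is a frames × atoms × 3 array in
Å with strictly increasing frame times (default: frame index; any mapping to
physical time, e.g. ns per frame, lives in configuration, since synthetic
data has no physical clock). Hydrogens are identified by the element field,
falling back to the first letter of the digit-stripped atom name.

File formats are multi-model PDB (read/write through biotite) and a columnar
text dialect (`frame,time,atom,x,y,z`, one row per atom per frame) chosen
because it is diff-able and byte-reproducible. No binary trajectory formats
are read; large ensembles should be converted or strided externally.

## Glycosidic states

χ is the dihedral O4′–C1′–N9–C4 (purines) / O4′–C1′–N1–C2 (pyrimidines),
computed with the standard atan2 construction, signed per the IUPAC
convention, range (−180°, 180°] (exactly −180° is reported as +180°).
*syn* is the half-open window [−90°, +90°), *anti* everything else. The
binary vocabulary and the window boundaries are a declared convention — the
two-region convention standard in the field — chosen for determinism; no
"high-anti" or intermediate classes are distinguished. Loop state labels
concatenate one letter per loop residue, strand 1 then strand 2, each 5′→3′;
with symmetry enabled the label and its strand-swapped reading are identified
and the lexicographic minimum (with "a" < "s") is the canonical form. The
tie-break is arbitrary but fixed.

## Symmetry-aware RMSD and clustering

`kabsch_rmsd` is the minimum least-squares RMSD over proper rotations and
translations (SVD solution with the determinant correction; reflections
excluded). `symmetry_min_rmsd` minimises additionally over the topology's
symmetry permutations, with ties broken toward the identity. Superposition
and measurement use the same atom selection (fit region = measure region),
typically the heavy atoms of the loop residues; by default that selection
includes the backbone and sugar atoms of those residues, not only the base,
recorded here as a configuration choice.

Two clusterings are provided:

* **Greedy leader** (default cutoff 1.0 Å): frames scanned in file order;
  each frame joins the nearest existing cluster whose *founding frame*
  (representative) lies within the cutoff, else founds a new cluster.
  First-frame representatives, lowest-RMSD assignment and in-order scan make
  the procedure fully deterministic given frame order. This is a
  reconstruction choice: leader clustering is the simplest deterministic
  scheme consistent with "assign snapshots to clusters at a fixed RMSD
  radius"; running centroids or different scan orders would be equally
  consistent and are deliberately not layered in.
* **Average linkage** (default cutoff 1.2 Å): hierarchical agglomeration
  (scipy) on the full symmetry-minimised distance matrix, cut at a distance
  threshold (not a cluster count, since the method is specified by an RMSD
  value). Representatives are medoids. The matrix is capped at 20,000 frames
  (≈3 GB); stride first for more. Symmetry defaults to on for both methods,
  switchable.

Population percentages always sum to 100 before filtering; reporting
aggregates clusters under `min_pct` (default 1%) into an explicit "other"
row so conservation stays visible.

## Convergence diagnostics

`TrajectoryPCA.fit` iterates superpose-on-average to its fixed point
(starting from frame 0; two passes typically suffice, and iterating makes
`transform` on the training data exactly consistent with the fitted
eigenvalues), then diagonalises the covariance of the fitted coordinates via
SVD (ddof = 1). Eigenvalues are Å², descending; eigenvectors orthonormal.
Projections RMS-fit each frame onto the fitted mean structure first.

`kld_curve` compares two segments of one projection mode. Both cumulative
histograms are Gaussian KDEs (Scott's-rule bandwidth, recorded in metadata)
evaluated at 300 equispaced centers on one shared grid spanning the union of
both full data ranges and normalised to unit mass. The divergence is the
asymmetric KLD(t) = Σᵢ P ln(P/Q) with P the first segment. Because finite
samples leave zero-mass bins, a floor of ε = 1e−10 is added to both
histograms before the log ratio and the masses renormalised; the result is
non-negative (Gibbs) and exactly zero for identical segments. The
eigenbasis is computed from the combined trajectory and both segments are
projected on it — per-segment bases would make P and Q incomparable; a
per-segment option exists for sensitivity checks. The evaluation grid is
200 cumulative fractions by default (configurable to per-frame).

`population_trace` reports trailing-window percentages of tracked clusters
after discarding a burn-in, both in frames; a configuration maps physical
windows (e.g. 500 ns with a 10 μs burn-in of a long run) to frame counts.

## Free-energy landscapes

`pmf2d` Boltzmann-inverts a plain 2D histogram (default 100×100 bins;
no KDE smoothing in 2D — kernel smoothing is used only for the 1D divergence
histograms): F = −kT ln(N/N_max), so the most populated bin anchors F = 0
and empty bins are masked. Surfaces are stored in kT; the conversion uses
k_B = 0.0019872041 kcal/(mol·K) (kT ≈ 0.596 kcal/mol at 300 K).

Basins are found by flooding bins in order of increasing F (8-neighbour
connectivity). At a saddle, any adjacent basin whose persistence (saddle F −
basin minimum F) is below `depth_threshold` (default 0.5 kT) merges into the
deepest adjacent basin — this suppresses shot-noise minima, since no
principled criterion for "distinct minima" exists at the histogram level.
Masked bins are traversed last at a ceiling just above the highest observed
bin, so disconnected sampling islands also meet the persistence rule, and
basins holding under `min_population_pct` (default 1%, mirroring the cluster
reporting filter) of all counts merge into the deepest basin. Validation
caveat: the F = 0 anchor is the *observed* maximum count, so absolute F
values carry the anchor bin's shot noise (≈ ±1/√N_max kT); quantitative
checks against closed forms should keep central-bin occupancy around 10³
counts (e.g. 50×50 bins for 2×10⁵ points).

## Hydrogen bonds

Geometric criteria: heavy-atom D···A ≤ 3.5 Å and, when the donor has an
explicit hydrogen (assigned by a 1.3 Å covalent cutoff within the residue),
D–H···A ≥ 135° for at least one such hydrogen. These are standard
MD-analysis defaults; topologies without hydrogens are scored on distance
alone. Same-residue pairs are excluded. The C/C mismatch classifier
restricts candidates to the cytosine Watson–Crick face — N4 donating, N3 and
O2 accepting, both directions — and reports per-frame counts plus ensemble
fractions of {0, 1, ≥2} bonds; it reports which pairs are bonded rather than
asserting a particular pairing.

## Synthetic ensembles

`build_duplex` places a rigid idealised nucleotide fragment (correct atom
names for the sugar/backbone, base rings including the cytosine N4/H41/H42,
N3, O2 face) on an A-form-like helix (rise 2.81 Å, twist 32.7°, C1′ radius
9.4 Å), with the second strand the C2 image of a standalone strand. The base
is rotated rigidly about the glycosidic axis so the computed χ hits its
target exactly (machine precision); default targets are the centres of the
conventional regions, syn = +25°, anti = −160°. The geometry is internally
consistent, not stereochemically refined — no force field is needed to test
analysis code.

`sample_ensemble` mixes named state templates with exact counts (or
multinomial weights, or a Markov chain over templates for pseudo-dynamics),
adds isotropic Gaussian coordinate noise (default σ = 0.15 Å), and appends
"noise" frames in which every loop residue is independently translated by a
random 6–12 Å vector — guaranteeing sub-threshold singleton clusters, the
structural analogue of the long tail of rare conformations in a real
ensemble. (A global rigid shift would be removed by superposition, which is
why the displacement is per-residue.) All draws come from a single seeded
generator in a documented order (labels, then noise shifts, then coordinate
noise), so outputs are bit-reproducible.

One construction subtlety: with a perfectly C2-symmetric build, the loop
states syn–anti/anti–syn and anti–syn/syn–anti are exact strand-swap images
of each other — symmetry-minimised RMSD 0 — and symmetry-aware clustering
would merge them, although in real ensembles they are geometrically distinct
states that merely share a canonical label. Each built-in GG/GG template
therefore carries a small template-specific rigid offset of the strand-1
loop residues (χ-preserving), and the generator verifies that all template
pairs are at least `min_separation` (default 4 Å) apart in symmetry-minimised
loop-heavy-atom RMSD, so clustering at a 1 Å cutoff provably recovers the
construction partition.

**What passing tests show — and don't.** Ground-truth recovery on these
ensembles exercises the full chain (selection, symmetry-minimised metric,
clustering, χ classification, canonical labelling, percentage reporting)
under conditions where the right answer is known exactly. It does not test
robustness to real-data features the generator omits: overlapping states,
anharmonic intra-state distributions, correlated backbone rearrangements,
solvent effects, or slow transitions that defeat the convergence
diagnostics at realistic trajectory lengths.

## Problem sizes and defaults

The reference experiments run at desk scale by design: the four-state
recovery uses 1,000 frames (425/358/40/34 + 143 noise) and completes in a
few seconds; the survey uses 100 structures; divergence checks use 5×10⁴
points per segment and landscape checks 2×10⁵ points. Defaults follow the
analysis conventions above: cutoffs 1.0 Å (greedy) / 1.2 Å (average
linkage), 1% reporting filter, 300 divergence bins, 100×100 landscape bins,
300 K.
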