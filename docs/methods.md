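# Methods

phytomotion analyses the structural catalytic cycle of histidine acid
phytases — in particular multiple inositol polyphosphate phosphatases
(MINPPs) that carry a U-loop insertion — at three levels: rigid-body
domain motion between conformational snapshots, geometric mapping of the
phytate specificity subsites around a bound hexakis-substituted inositol
ligand, and sequence-level detection of the signature motifs and the
U-loop itself.  This note records the models, the parameters that matter,
the numerical choices, and the limits of what the synthetic benchmarks
demonstrate.

## Rigid-body geometry

Superposition solves the weighted orthogonal Procrustes problem with
Horn's quaternion method: the optimal rotation is the eigenvector of a
4x4 symmetric matrix for its largest eigenvalue.  This formulation cannot
return a reflection (the determinant is +1 by construction) and remains
well behaved for nearly degenerate point sets; a near-collinear input
additionally emits a conditioning warning because rotation about the line
is unconstrained.  Fewer than three paired points is an error.

Any rigid displacement is reported in Chasles (screw) form: a rotation
angle about an axis in space plus a signed translation (pitch) along it.
The angle comes from the rotation-matrix trace, the axis from the
skew-symmetric part (falling back to the +1 eigenvector within a degree
of 180°, where the skew part vanishes), and the axis point is the point
on the axis closest to the origin, obtained from a constrained
least-squares solve.  Rotations below 0.1° are reported as pure
translations with the axis along the translation vector; recomposition of
a decomposed transform agrees with the original to better than 1e-6 Å on
probe points.  Angles are reported in degrees to one decimal.

## Domain-motion analysis

The decomposition of a conformational change into quasi-rigid domains
follows the classic sliding-window rotation-vector scheme:

1. **Rotation vectors.** Residues are paired across the two structures by
   identical author numbering.  For each residue with a full window
   (default 5 residues, odd, consecutive numbering on both sides) the two
   C-alpha windows are superposed and the local rotation stored as an
   axis-angle vector in degrees.  Windows whose fit RMSD exceeds
   max(0.05 Å, 3x the median window RMSD) span a hinge; they are flagged
   as boundary windows and excluded from clustering (the adaptive term
   keeps the flag meaningful at any noise level, the floor keeps
   numerical jitter from being flagged at zero noise).
2. **Clustering.** k-means over the rotation vectors for k = 1, 2, …
   (fixed seed, 10 restarts, so reports are deterministic).  Because
   short-window rotation vectors are noise-dominated when the interdomain
   rotation is small, the two-domain case is additionally seeded by an
   exhaustive contiguous-split scan: every chain split point is scored by
   the summed rigid-fit residual of its two sides and the minimum taken.
   Each seeding is refined by iterating "fit a rigid transform per
   domain; reassign every residue to the domain whose transform best
   predicts its displacement", which operates on coordinates rather than
   rotation vectors and cleans the hinge boundaries.
3. **Split acceptance.** A k+1-cluster solution replaces the k-cluster
   one only if (a) chain-contiguous segments shorter than the window are
   discarded and every remaining domain still has at least
   `min_domain_size` (default 20) residues, (b) every domain pair moves
   more between than within domains — the interdomain-to-intradomain
   displacement ratio, taken as the smaller of the two directed ratios
   with the internal deformation floored at 0.01 Å, is at least
   `ratio_threshold` (default 1.0) — and (c) the finer solution does not
   discard more than 10% of the residues the coarser one had assigned.
   Criterion (c) exists because the displacement refinement can make a
   noise-driven split of a genuinely rigid body self-consistent by
   sorting residues on their noise realisation; such splits always
   fragment the chain and fail (c).  The window, minimum domain size and
   ratio threshold defaults are the published defaults of the established
   domain-motion method this reimplements; all are exposed as
   configuration.
4. **Interdomain motion.** The largest domain is the fixed domain.  After
   superposing the two structures on its C-alpha set, the moving domain's
   residual transform is decomposed into a screw; its angle is the
   reported domain rotation.  Percent closure is 100·sin²γ, with γ the
   angle between the screw axis and the line joining the fixed- and
   moving-domain centroids (averaged over the two fitted states): a hinge
   axis perpendicular to the centroid line closes the domains onto each
   other like a book (100%), an axis along the line twists them (0%).
   This reproduces both limiting cases exactly on synthetic pairs built
   with a known axis.
5. **Hinge residues.** Residues in the chain-contiguous junction regions
   between differently assigned segments, plus residues whose C-alpha
   lies within 5.5 Å of the screw axis within two windows of a junction,
   grouped into contiguous segments.  This is a geometric reconstruction;
   it is validated by interval overlap with the conserved motifs that
   bracket the hinge in the real enzyme, not by exact residue lists.

For a snapshot series (apo → substrate-analog → intermediate → product)
every state is compared against the reference snapshot using the common
decomposition taken from the pair with the largest motion, so that
"percent closure" means the same thing across the cycle.

## Specificity-subsite mapping

The six substituent groups of a bound hexakis-substituted inositol
(sulfate groups in the nonhydrolyzable analog, phosphates in the
substrate) define six specificity pockets.  Pocket A holds the analog of
the scissile phosphate, identified as the substituent whose central S/P
atom is nearest the catalytic histidine's imidazole nitrogens (NE2/ND1).
The remaining pockets are labelled B–F by traversing the ring positions
in cyclically decreasing order from A.  This algebraic rule is the
orientation-free equivalent of the counterclockwise visual convention
(viewing the ring from behind toward the catalytic centre) and is pinned
by the anchor: A at ring position 6 places the axial 2-substituent in
pocket E.

A pocket's contacts are all polymer residues with any heavy atom within
the cutoff (default 6.0 Å) of any atom of the substituent group — the
central S/P, its terminal oxygens, and the ring-linking oxygen.  This is
the most inclusive reading of a "within 6 Å of each substituent" rule and
makes pocket populations sensitive to bulky side chains, which is the
property of interest when comparing enzymes.  Contacts are computed per
ligand conformer; protein side-chain altlocs are paired with the ligand
conformer by matching altloc label, else by highest occupancy.  Both the
all-atom and the side-chain-only minimum distances are reported because
published "close within" statements do not always say which was meant.

Disulfides are cysteine SG–SG pairs within 2.3 Å (a typical S–S bond is
2.05 Å); polar contacts are N/O…N/O heavy-atom pairs within 3.5 Å.
Hydrogens, when present, are excluded from all distance operations.
Per-residue displacement between two states is measured after a
fixed-domain C-alpha superposition and classed at 2.0/4.0 Å on the
C-alpha displacement (the maximum main-chain displacement over N, CA, C,
O is also reported, since figures that colour whole residues may reflect
either metric).

## Ligand extraction

Ring atoms are identified from a per-component naming table (C1…C6 for
the inositol hexakissulfate/hexakisphosphate components); unknown
components fall back to six-cycle detection on the covalent-distance
graph (bond when closer than 1.8 Å), with a deterministic but arbitrary
starting position.  Substituent groups are then walked geometrically:
ring carbon → linking O → central S/P → terminal O atoms.  Each altloc
conformer yields its own group carrying its refined occupancy, because
static disorder of the bound analog (two orientations with unequal
occupancies) is itself a finding worth reporting.

## Sequence analysis

The motif scanner matches position-by-position against token patterns
(literal, any, hydrophobic class, bracketed class) rather than compiling
to regular expressions, so regex implementations remain an independent
verification route.  Patterns: RHGXRXh (h ∈ {A,V,L,I,M,F,W,Y}; the
hydrophobic set is a choice, as the family descriptions do not enumerate
it), HD and HAE (both proton-donor motifs are searched, since MINPPs
carry HAE where other family members carry HD), GXLTXXG, DAAM, and the
extended consensus RHGXRXL(S/T)SXK.  All coordinates are reported in
author numbering via a configurable offset.

U-loop detection has two modes.  Alignment mode takes a precomputed
alignment with a non-loop reference and finds the longest
reference-gapped block of at least `min_insert` (default 8) columns
between the RHGXRXh and DAAM anchors; this is the authoritative mode and
the one validated against planted insertions.  Motif-anchored mode needs
no reference: the window ends immediately before the DAAM motif (the
conserved block that closes the loop region) and starts at the first of
at least two cysteines found within 70 residues upstream.  It therefore
only anchors cysteine-bearing loops and tends to underestimate the loop
length; annotations record which mode produced them.  Alignment
computation itself (e.g. MUSCLE/MAFFT) is deliberately out of scope —
alignments are inputs.

Classification is by length first: type A requires ≥ 35 residues *and*
at least two cysteines inside the loop (the disulfide-competent long
loop); ≥ 35 residues without the cysteine pair, or 20–34 residues, is
type B; `min_insert`–19 residues is type C.  The numeric thresholds are
reconstructions of a qualitative long/medium/short scheme with a
44-residue, two-cysteine type-A exemplar; they are configuration, and
reports carry the cysteine count so a reader can re-cut.  Loops shorter
than `min_insert` classify as none.

## Synthetic data: what it emulates, and what it does not

`make_motion_pair` builds a two-body protein: each body is a C-alpha
trace wound over a sphere at protein-like packing density (radius
1.07·√n Å, 3.8 Å spacing) with dummy N/C/O atoms placed from local chain
frames, the two bodies joined tangentially through their chain termini.
The default sizes (120 fixed / 90 moving residues) are proportioned like
a phytase core and its moving lid at reduced scale.  Model B applies a
known screw to the moving body only; Gaussian noise is then added to both
models independently, so the generating screw remains the exact ground
truth of the noiseless signal.  `make_closure_pair` places the hinge axis
at a controlled angle to the inter-centroid line, passing through the
moving-body centroid so the expected percent closure (100·sin² of that
angle) is exact by construction.  A spherical-spiral body is genuinely
three-dimensional and so constrains rotation about every axis; this
matters because rotation-recovery accuracy scales like σ/(r_g·√N) and a
quasi-linear backbone would be ill-conditioned about its own axis in a
way real domains are not.

`make_ligand_site` builds a planar six-ring with sulfate-like groups
(linking O, central S, three terminal O tilted back toward the ring so
the central S is the outermost group atom), a histidine facing a chosen
ring position, and shell residues whose nearest atom sits exactly at a
target distance from their subsite's central S along the outward radial
direction.  Achieved distances are verified at generation to ±0.05 Å.
`make_uloop_family` plants the signature motifs at their canonical MINPP
author positions (RHGXRXh at 44, GXLTXXG at 98, HAE at 399) on a random
backbone drawn from an alphabet that cannot create spurious motif hits,
inserts loops of controlled length and cysteine content immediately
before the conserved block preceding DAAM in half the members, and emits
the implied gapped alignment.

What passing these benchmarks does **not** show: the synthetic bodies are
ideally rigid with isotropic noise, whereas real domains deform
internally, carry correlated displacements (TLS-like), and differ between
crystal forms for reasons other than the hinge motion; the synthetic
ligand site has no second conformer, no solvent and idealized geometry;
the sequence backbone has no real compositional bias or homology
structure.  Agreement with published numbers for the real enzyme is
therefore checked separately, against the deposited structures and
sequences, and only the geometry/logic of the pipeline — not its
robustness to crystallographic reality — is certified by the synthetic
suite.

## Numerical choices and degenerate inputs

* Determinism everywhere: k-means is seeded (default 17) and restarted
  10 times; generators are pure functions of their seeded specs with
  byte-stable file output; report JSON is sorted-key with fixed precision
  (angles 0.1°, distances 0.01 Å, closure 0.1 point).
* Identical structures: all rotation vectors vanish, clustering returns a
  single domain, and the hinge report is a null report (angle 0, closure
  0) rather than an error.  The same null report covers any pair where no
  valid split exists.
* Percent closure is clamped to [0, 100] by construction of the sin²
  formula; the screw angle is non-negative by the trace convention, and
  swapping the input structures inverts the axis while preserving angle
  and closure.
* Author numbering (not sequential index) is the coordinate system for
  all residue references; insertion codes order alphabetically after
  their parent number.  Pairing across structures requires identical
  (number, insertion code).
* Occupancy sums over conformers are validated to at most 1 + 1e-6.

## Problem sizes

The benchmark suite and the acceptance script run 100 seeded motion pairs
of 210 residues, 20 pairs at the maximum noise level, one synthetic
ligand site, a 10,000-residue random sequence scan, and four sequence
families of six members — sizes chosen so the whole study re-runs from
scratch in well under a minute per stage on a single CPU while keeping
every estimate's sampling error far below the tolerances being checked.

## Known limitations

* The hinge-residue rule (junction segments plus 5.5 Å axis proximity) is
  a geometric reconstruction; different published tools draw hinge
  boundaries differently, so it is validated by interval overlap only.
* Percent closure depends on the centroid convention when domains are
  asymmetric and partially assigned; the average-state convention used
  here reproduces the limiting cases exactly but can differ by a point or
  two from other conventions on real structures.
* Motif-anchored U-loop detection cannot find cysteine-free loops and
  underestimates loop length; use alignment mode when a reference is
  available.
* With two monomers per asymmetric unit, reported values can differ
  between chains; the pipeline reports per-chain values and the series
  command flags disagreement rather than averaging it away.
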