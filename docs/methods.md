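# Methods

This note documents the statistical models, conventions and numerical
choices behind `sinefactory`, and what its synthetic-data tests do and do
not demonstrate about real data.

## Differential-acetylation window scan

Two deduplicated tag libraries (condition *a*, control *b*) of sizes
N_a and N_b are compared in windows of width *w* = 2000 bp slid at step
*s* = 500 bp along each chromosome. Conditional on the window total
n = k_a + k_b, the condition count under the no-change null is

    k_a | n  ~  Binomial(n, p0),     p0 = N_a / (N_a + N_b),

so p0 absorbs the depth difference between libraries and no cross-sample
normalization is needed. Two one-sided tail p-values are computed per
window, each including the observed count:

    p_inc = P(X >= k_a),    p_dec = P(X <= k_a).

A window is called at p < 1e-3 (strict) in either direction; maximal runs
of overlapping-or-abutting same-direction significant windows are merged
into +dAc / -dAc regions whose score is the peak -log10(p). Conventions:

- Coordinates are 0-based half-open throughout; a tag sits at its mapped
  5' end (no fragment shift); the dedup key is (chromosome, position,
  strand), so opposite-strand tags at one position count as two molecules.
- The step of 500 bp is a package choice (region widths then quantize at
  0.5 kbp); it and every other scan parameter are configurable.
- The final partial window at a chromosome end is emitted with a truncated
  width and a flag, and excluded from region calling by default.
- Track serialization writes signed heights (-log10 p for increases,
  log10 p i.e. negative for decreases) as bedGraph lines inside a
  `track type=wiggle_0` container; bedGraph is 0-based half-open by its
  standard, fixedStep/variableStep declarations are 1-based and the reader
  converts.

### FDR estimate

The per-scan false-discovery estimate is *expected false positives over
observed positives*: for each tested window (n > 0; empty windows can never
be significant and are excluded) the exact null probability of either tail
falling below the threshold is computed from the discrete binomial —
locating the upper and lower rejection runs of k directly — and summed;
the sum is divided by the observed number of significant windows and capped
at 1, an FDR being a proportion. This is one of several defensible
estimators; it is exact under the binomial null, conditional on the
observed window totals.

### Calibration behaviour (what tests show)

Because the binomial is discrete and the tails include the observed count,
the test is conservative: at window totals around n = 40 the realized
rejection rate at a nominal 1e-2 is ~0.006, approaching ~0.009 only at
n ≈ 400. The unit suite asserts the property the implementation can
guarantee — that the observed discovery count on a null simulation matches
the discreteness-aware model expectation within sampling noise — rather
than equality with the nominal level. Recovery of 3x-enriched spiked
windows exceeds 90% from ~25 background tags per window per library
upward. Merged regions systematically overshoot a planted enriched
interval by up to two steps per side: a window overlapping half of a
3x-spiked interval is genuinely ~2x enriched and is correctly called with
appreciable probability, so the union-of-significant-windows region
definition cannot localize boundaries to within one step at depths that
meet the sensitivity target. Users who need tight boundaries should
post-process regions (e.g. trim to the peak window); the caller reports
the union faithfully.

## Gene grouping and genomic context

Expression-based groups follow fixed thresholds on a precomputed
differential-expression table: NI (induced) requires fold >= 1.24
(inclusive) with adjusted p < 0.05; NR the reciprocal; CE requires
detection in both conditions absent a differential call; CS detection in
neither. Genes detected in exactly one condition without a differential
call have no defined group and are left "unassigned" with a warning.
Region context is exclusive with TSS-overlap taking precedence over gene
body; the three categories partition any region set.

## TSS-relative profiles

Tag metaprofiles bin tag 5' positions into 100-bp bins on TSS-relative
coordinates, with minus-strand genes coordinate-flipped so downstream is
positive; bins extending past a chromosome end are masked out of group
averages. The per-gene promoter statistic summarized in box plots is the
mean count per 100-bp bin over [0, +500) bp.

The acetylated-SINE profile counts, for each plotted offset o in
-100..+100 kbp at 5-kbp intervals, SINE elements whose midpoint falls in
the 50-kbp window centred on o. The window is closed at both ends and
membership uses the element midpoint, so a single element contributes to a
contiguous run of offsets without boundary double-counting ambiguity;
left-aligned windows are available via configuration. "De novo acetylated"
SINEs are SINE-class repeats with >= 1 bp overlap (half-open) with a +dAc
region. Per-offset NI-vs-CE comparisons use the two-tailed Mann-Whitney
test.

## Rank and count statistics

Fisher's exact test (two-sided) is used for repeat-family enrichment
(frequencies reported per 1000 regions against size-matched random
backgrounds), motif over-representation, and colocalization comparisons.
The Mann-Whitney implementation enumerates all C(n, n_x) group assignments
of the pooled sample exactly for combined n <= 20 — ties are handled by
the midrank U — and otherwise uses the normal approximation with tie and
continuity corrections. Two-sided p is min(1, 2·min(lower tail, upper
tail)), tails including the observed U. Background intervals are sampled
uniformly over allowed placements; the TSS-overlapping constraint anchors
on a uniformly chosen TSS and rejection-corrects for multiply-covered
placements so uniformity is preserved.

## B-box motif analysis

Sequences are scored against a position-weight matrix in log2-odds bits
against a uniform background; N in a scored window contributes 0
(background-neutral). Both strands are scanned, reverse-strand scores
being computed on the reverse complement and mapped back to forward
offsets. The published B-box-like ETC matrix is not reproduced here: the
shipped default PWM is a synthetic stand-in built from a 16-bp consensus
whose informative core is the canonical RNAPIII type-2 B box
(GTTCGAANNC), flanked by neutral N columns, with a uniform pseudocount of
0.25 per base; any plain-text L x 4 matrix can be loaded in its place and
all thresholds are expressed as fractions of the maximal score so they
transfer. The default hit threshold is 80% of maximal. Ordinal
B-box-prediction categories use edges at 80 / 87.5 / 95% of maximal with
an implicit top edge at the maximum itself; edges are right-closed into
the higher bin, so a perfect-consensus hit is "++++" and scores below 80%
are no-calls. Per-sequence presence/absence feeds the over-representation
Fisher test.

## 3D immuno-DNA FISH analysis

Stacks are (z, y, x) with physical voxel sizes (dx, dy, dz) nm; dz
defaults to the 200-nm confocal z-step. The nucleus is the largest
26-connected component above the Otsu threshold of the DAPI channel,
hole-filled per slice; the contract is one nucleus per field (crop
multi-cell fields upstream). RNAPII-positive voxels are those strictly
above mean + k·SD of the channel within the nucleus (k = 1; the
population-n SD variant, a documented package choice). Objects are
26-connected
supra-threshold components of at least 2 voxels, with intensity-weighted
centroids at physical coordinates ((i + 0.5)·d per axis). The FISH channel
uses the same mean + k·SD rule with k = 2 by default (the reference tool's
shape-and-intensity rule is not published; this is a documented stand-in).
Locus-to-factory distance is the minimum anisotropic Euclidean distance
from the FISH centroid to a positive voxel center, over all directions and
z-planes; colocalization is distance <= 225 nm (inclusive). Transcription
factories are counted as positive components passing the volume floor;
foci closer than one voxel merge — the method's resolution limit. A single
scalar colocalization threshold is used without axial rescaling.

## Synthetic data: what it emulates, and what it does not

All generators route randomness through one seeded `numpy.random.Generator`
and are byte-deterministic per seed.

- **Tag libraries.** Background tags are uniform over the genome at a
  stated per-window depth (default 20 per 2-kb window per library; the
  spike-recovery study uses 25, where >= 90% sensitivity is attainable);
  spiked intervals multiply the local rate by r in the condition library
  only. The stated library size is the realized size — spikes redistribute
  depth rather than add to it, as sequencing a library to fixed depth
  does, so p0 carries no artefactual shift. Duplicate (position, strand)
  draws are resampled, so emitted libraries are already deduplicated.
  Not emulated: mappability structure, GC bias, fragment-length effects,
  clonal amplification hotspots (a hotspot option exists for robustness
  experiments). Passing tests therefore demonstrate correctness of the
  count model, not robustness to real-library artefacts.
- **Annotation.** Gene cohorts are laid out at fixed spacing with margins
  so profile windows never truncate; every group shares a uniform baseline
  of acetylated SINEs (mean 2 per gene over ±125 kbp) and group rules add
  a surplus (default: NI, Poisson mean 3 uniform in +20..+75 kbp). The
  emitted expression table is constructed to round-trip exactly through
  the classifier. Real gene-density heterogeneity and clustered repeats
  are not emulated.
- **Sequences.** I.i.d. uniform-composition backgrounds with the PWM
  consensus planted at recorded offsets in a designated fraction; neutral
  consensus positions are realized randomly, leaving planted windows
  maximal-scoring.
- **Image stacks.** An ellipsoid DAPI nucleus, Gaussian RNAPII foci
  (isotropic 60-nm sigma in physical units, anisotropic in voxels,
  amplitude 300 over background 10 with Gaussian read noise SD 2 — bright
  enough that foci dominate the in-nucleus variance, as RNAPII-ser5P
  staining does, putting the mean+1SD threshold well clear of the noise),
  and FISH spots placed at exact requested distances from their nearest
  focus (other foci are kept farther away). No Airy/PSF model, chromatic
  shift or photobleaching: the generator validates the distance logic and
  thresholding conventions, not optical realism. Measured
  nearest-positive-voxel distances are biased below the planted
  centre-to-centre distance by the positive-blob radius (~150 nm at the
  default rendering), which stays within the one-voxel-diagonal tolerance
  used in the recovery checks.

## Problem sizes

The shipped studies are sized for interactive runs: 10^4 windows for null
calibration (tiled, at 80 tags/window so the discrete test is close to
nominal), 50 spiked windows over a 2.55-Mb genome, 100 genes per group on
a 61-Mb chromosome for the SINE band, 200 sequences for motif recovery,
and 50 synthetic cells (plus one 200-focus field) for imaging. The whole
acceptance computation completes in well under a minute; all sizes scale
through the spec dataclasses.

## Known limitations

- The FDR estimator is conditional on observed window totals and ignores
  inter-window correlation from overlapping sliding windows.
- Exact Mann-Whitney enumeration is O(C(n, n_x)) and switches to the
  normal approximation above combined n = 20.
- Region boundaries are unions of 2-kb windows and overshoot true
  enrichment boundaries by up to two steps (see calibration section).
- The B-box PWM is a stand-in; scores and category calls are comparable
  only within a matrix, which is why thresholds are relative to the
  maximal score.
- Imaging assumes one nucleus per field and voxel-center distance
  semantics; sub-voxel spot fitting is out of scope.
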