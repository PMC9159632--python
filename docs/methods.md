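# Methods

This note documents the models implemented in `mucoquant`, the parameter
choices that matter, and what the synthetic-data generators do and do not
emulate.

## Segmentation

**Adaptive threshold.**  A pixel is foreground iff
`I(x) > mean_w(x) + s * (I_max - I_min)`, where `mean_w` is the mean over a
square window (default 51 px, larger than any mucocyst at the intended
magnification; edge pixels use the in-bounds part of the window) and the
range is global.  The sensitivity `s` is dimensionless and independent of
the image's intensity scale, and the mask is monotone nonincreasing in `s`,
which makes sensitivity sweeps well ordered.  MATLAB-style adaptive
thresholding exposes a similar "sensitivity" knob whose exact formula is
proprietary; this rule is a documented stand-in chosen for its provable
monotonicity, not a claim of numerical equivalence.  A guard of
`1e-12 * max(1, |I|_max)` absorbs floating-point wobble in the windowed
mean so that constant images are always all-background.

**Morphology.**  Optional binary opening then closing with disk structuring
elements (radius 0 skips the step).  Note that discrete disk openings clip
the corners of rectangular objects — an unavoidable property of rasterized
disks — so cleanup defaults to off; the `min_area` filter (default 4 px²)
suppresses shot noise instead.

**Features.**  8-connected components restricted to the cell mask.  Ellipse
parameters come from second central moments of the pixel coordinates:
orientation `= 1/2 * atan2(2*mu11, mu20 - mu02)` folded into [0°, 180°),
measured from the +column axis toward the +row axis; axis lengths
`= 4 * sqrt(eigenvalue)` of the coordinate covariance, so a rendered solid
ellipse recovers its full axis lengths (variance along the major axis of a
solid ellipse is `a²/4`).  Centroids are intensity-unweighted.

## Colocalization

Observed statistic: the fraction of Mdl features sharing at least one pixel
with any Grl feature — a parameter-free, object-based definition of
"overlap".  The null rigidly translates (no rotation) each Mdl feature's
pixel set to a uniformly random position fully inside the cell mask;
features may land on each other.  Uniformity over *valid translations* is
implemented exactly by enumerating all admissible placements (a binary
erosion of the mask by the feature's footprint) and sampling among them,
which is equivalent to rejection sampling but deterministic in cost.  For
point-like features this null converges to the Grl coverage fraction of the
cell, which the tests verify against a binomial oracle.

## Tip polarity

Each overlapping Mdl feature is assigned to the Grl feature it shares the
most pixels with (ties to the smaller label).  Two statistics per pair:

* **angle**: acute angle in [0°, 90°] between the Grl major axis
  (undirected) and the centroid-connecting segment — invariant to axis
  reversal and to swapping the endpoints; undefined (and excluded from
  angle samples, but retained as offset 0) when the centroids coincide;
* **offset**: centroid distance normalized to half the Grl major-axis
  length — 1 at the ellipse vertex, i.e. the organelle tip.

**Null.**  The punctum centroid is re-placed uniformly inside the *fitted*
ellipse of the paired organelle (rather than its raw pixel set): the
organelle is modelled exactly as its long/short-axis summary, and the
choice admits analytic oracles — for a circular fit the null offset has
density 2r on [0, 1] (mean 2/3) and the null angle is Uniform(0°, 90°)
(mean 45°).  Sampling maps uniform unit-disk draws through the ellipse
axes, which yields offsets and angles directly in the axis frame.

**Testing.**  Observed statistics are pooled across all pairs (the
experimental design pools speckles across cells), the null pools R draws
per pair (default 1000), and both angle and offset samples are compared to
their nulls with the two-sample KS test, two-sided, with the asymptotic
Kolmogorov p-value at `sqrt(n1*n2/(n1+n2)) * D`.  Which of the two
statistics carries the inference is left to the user; the package reports
both.  Type-I calibration is assessed on the **angle** statistic: for
puncta planted at the organelle centroid (tip bias β = 0) the measured
displacement is pure, approximately isotropic measurement noise, so its
angle distribution matches the null's angular component; the offset
distribution under β = 0 is a point mass near zero by construction and has
no type-I interpretation against a uniform-in-ellipse null.

## Docking

The peripheral fraction is the Grl intensity inside a band (cell mask minus
its erosion by a disk) divided by the total in-cell intensity.  Hand-drawn
peripheral selections are replaced by this reproducible fixed-width band;
the width defaults to 10% of the cell's equivalent radius and is exposed as
a parameter because no principled width exists.  The statistic is invariant
under global intensity rescaling and nondecreasing in band width.  Strain
comparisons use classical single-factor ANOVA (`F = MS_between/MS_within`).

## Pooled-segregant mapping

Sites are scored with the **allelic contrast**
`alt_MUT/depth_MUT - alt_WT/depth_WT` ∈ [−1, 1], the simplest interpretable
pooled-frequency contrast (external mapping suites implement related but
undocumented scores; exact numeric agreement with them is not claimed).
The pipeline: coverage filter (≥ 100× in both pools by default), centred
sliding-window mean per chromosome (200 kb default), normalization by the
genome-wide maximum, peak region = the longest contiguous run of sites at
≥ 90% of the maximum on the chromosome carrying it (ties resolved toward
the run containing the maximum), then candidate refiltering inside the
region: depth ≥ 5× in both pools, mutant-pool alt frequency ≥ 0.9 ("looks
homozygous"), wildtype-pool alt frequency < 0.9, ranked by impact category
(HIGH > MODERATE > LOW > MODIFIER > NONE), then descending contrast, then
position.

With pools of 32 whole-genome-homozygote clones and ~1 cM/Mb, the linkage
signal has a **multi-megabase flat top**: between the recombination
breakpoints flanking the causal site across all informative clones the
clone-level allele frequencies are identical, and only read-sampling noise
distinguishes sites.  The peak-region *interval* is therefore the
meaningful output (a few Mb, matching the resolution such crosses achieve
in practice), while the argmax position within the plateau is noise-driven.
The longest-run rule makes region detection robust to the sparsity induced
by the coverage filter (Poisson(90) depths leave ~2.6% of sites at ≥ 100×
in both pools).

## Synthetic data

**Images** emulate a 100× widefield midsection of a *Tetrahymena* cell:
an elliptical cell (default 36 × 24 µm at 0.08 µm/px in a 512 × 512 frame)
containing `n_mucocysts` (default 25) non-overlapping elliptical organelles
(semi-axes 0.5 × 0.25 µm), placed either **docked** — centred just inside
the cell boundary, major axis perpendicular to it, tip pointing outward —
or **cytoplasmic** (uniform position and orientation).  One disk punctum
(radius 0.15 µm) per organelle sits at normalized major-axis distance
β from the organelle centroid toward the tip; β = 0 is centre placement,
β = 1 the tip.  Both channels get a Gaussian PSF (σ = 0.08 µm), optional
Poisson photon noise, Gaussian read noise (σ = 0.02 of the unit organelle
amplitude), and a few dim autofluorescent blobs common to both channels.
Placement uses bounded rejection sampling (500 attempts per organelle);
ground truth records the pre-noise geometry.  Not emulated: 3-D structure,
depth-dependent blur, uneven illumination, organelle intensity variation,
cell-shape irregularity — so passing tests demonstrate correctness of the
measurement pipeline on idealized optics, not robustness to every real
imaging artifact.

**Crosses** emulate sequencing of two pools of 32 whole-genome-homozygote
F2 clones (mutant-phenotype and wildtype-phenotype) over five 10 Mb
chromosomes with markers every 10 kb.  Each clone inherits one recombinant
chromatid per chromosome; crossovers are a Poisson process (Haldane's map
function, no interference) at 1 cM/Mb, anchored at the causal locus
(selected allele) on the causal chromosome and at a fair coin on the
others.  Pool allele frequency is the clone average; reads are
Poisson-depth (mean 90) with binomial alt counts.  `phenotyping_error`
(default 0.01) is the probability a clone is mis-assigned to the other
pool: a small, realistic misclassification rate for a plate-level secretion
assay, which also keeps read counts at fixated sites from being literally
noise-free (a Binomial(n, 1) artifact no real pool shows).  The expected
mutant-pool frequency at a marker at distance d Mb is
`(1-e)(1-r) + e*r` with `r = (1 - exp(-2*d*c/100))/2`.  Background
mutagenesis-induced variants are annotated with impacts drawn from a
SnpEff-like distribution at rate 0.002 per marker; all other markers are
`NONE`.  Not emulated: sequencing/base-call error, mapping bias,
macronuclear-to-micronuclear coordinate rebasing, meiotic interference.

## Numerical choices and degenerate inputs

* Pixel coordinates are 0-based (row, col); genomic positions 1-based —
  the dominant conventions of the respective formats.  BED output is
  0-based half-open.
* Angles: undirected axes fold into [0°, 180°); pair angles into [0°, 90°].
* Degenerate fits (zero axis length) raise measurement errors rather than
  returning NaNs; zero-depth sites are excluded from contrast scoring.
* An all-nonpositive linkage track stays zero rather than being divided by
  its maximum; an eroded-away docking band falls back to the whole mask
  with a logged warning.
* KS p-values are clipped into (0, 1]; samples of ≥ 4 observations are
  advisable for the asymptotic approximation.
* All stochastic operations take explicit seeds and are bit-reproducible;
  pooled analyses derive per-pair seeds from one root seed via
  `SeedSequence.spawn`.

## Test problem sizes

The suite runs its statistical checks at deliberately compact sizes chosen
as a sensible compute budget for a routine test run: calibration uses 200
simulated 256 × 256 cells (~12 organelles each), power uses 100 experiments
of 32 pairs, analytic null oracles use 10⁵ draws, and causal-locus recovery
uses 100 replicate crosses at the default design.  Larger runs only shrink
the Monte-Carlo error bands already accounted for in the assertions.

## Known limitations

* The adaptive-threshold rule approximates, but is not identical to, the
  proprietary "sensitivity" thresholding of common acquisition software.
* The peak-region rule replaces human visual inspection of linkage plots;
  on real, noisier data the `frac_of_max`, window and depth parameters may
  need adjustment.
* The allelic-contrast score ignores depth differences between sites
  (no likelihood weighting); with very uneven coverage a depth-aware score
  would be preferable.
* Randomization nulls translate features without rotation; for strongly
  anisotropic features inside narrow masks a rotation-aware null could
  differ.
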