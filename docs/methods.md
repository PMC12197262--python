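# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `choroid_sps`, in the order data flows through the package.

## Image model and conventions

Images are 2-D rasters on a fixed 0–255 intensity scale, stored as floats
internally and written as 8-bit (round half-up, clamp).  The choice of an
8-bit scale is deliberate: reported COID values in the tens (≈ 57–72) are
only meaningful on a 0–255 scale.  Arrays are row-major `(row, col)`,
0-based, row 0 at the vitreous (top) side, so a 1024 × 992 export is an
array of shape `(992, 1024)`.  RGB inputs collapse to Rec. 601 luma
(0.299, 0.587, 0.114) — the common default of mainstream imaging
toolchains; 16-bit inputs rescale linearly.  Multi-frame TIFFs are rejected
loudly rather than silently reading frame 0.

## Sharpening

Unsharp masking with three controls: Gaussian σ (`sharpen_radius`, default
1.0 px), gain (`sharpen_amount`, default 0.8) and a detail threshold
(default 0, 0–255 units) below which pixels pass through unchanged.  The
blur truncates at 4σ with a reflective border.  Defaults mirror the
documented defaults of the sharpening function used in the original
interactive workflow, as the least-surprise choice.  Sharpening exists to
help segmentation find boundaries; the density metric deliberately does not
use it (below).

## SLIC superpixels

Written from scratch for single-channel images (OCT B-scans have no
color; `d_c` is a plain intensity difference, no CIELAB conversion).

* **Initialization**: centers on an integer grid with spacing
  `round(S)`, `S = sqrt(H·W/K)`, starting at `round(S)//2` (the canonical
  regular-grid convention); when integer rounding would produce fewer than
  K centers (tiny K), a fractional per-axis grid guarantees at least K.
  Each center then moves to the lowest-gradient position in its 3×3
  neighborhood (gradient = sum of squared forward differences), avoiding
  initialization on an edge.
* **Iteration** (default 10, the convergence figure from the superpixel
  literature): each center claims pixels in its 2S × 2S window minimizing
  `D = sqrt(d_c² + (d_s/S)²·m²)`; ties go to the lower center index
  (determinism); centers update to the mean (row, col, intensity) of their
  pixels.
* **Connectivity enforcement**: 4-connected components smaller than
  `min_size_factor` (default 0.25) times the mean superpixel size merge
  into the adjacent component with the longest shared border, preferring
  components at least as large; remaining components each become one label,
  renumbered densely 1..N.  N may therefore differ from K in both
  directions.
* `seed` is accepted for interface stability but is a no-op: plain SLIC has
  no randomness.

Defaults `K = 300`, `m = 20` (on the 0–255 scale), sized for 1024 × 992
scans: ≈ 58 px superpixel diameter, small enough to follow choroidal
boundaries.  Note that compactness scales differ across implementations:
scikit-image rescales images to [0, 1] before weighting, so `m` here
corresponds to `m/(I_max − I_min)` there.  The test suite compares the two
implementations at matched strong compactness, where the joint metric is
well-conditioned; at low compactness under heavy speckle the assignment
problem has many near-tied minima and independent implementations
legitimately diverge.

## Selection, smoothing, metrics

Interactive click-selection is replaced by two reproducible forms: an
explicit label set, or `auto_select`, which takes every superpixel with at
least `selection_overlap` (default 0.5) of its area inside a reference
mask.  The selected mask is smoothed by opening-then-closing with the
closed-ball disk `B_r` (`dr² + dc² ≤ r²`; r = 1 is the 5-pixel cross,
r = 0 the identity).  Default `r = 5` at full scan scale: large enough to
remove single-superpixel jaggedness, small relative to choroid thickness.

Out-of-bounds pixels count as background for **both** erosion and
dilation.  Consequence worth knowing: closing is not extensive for
foreground touching the image border (a corner pixel is eroded away after
dilation); the classical ordering `opening(M) ⊆ M ⊆ closing(M)` holds for
masks keeping an r-wide margin.  A related discrete-morphology fact: disk
opening shaves the corners of a perfect square (5 px per corner at r = 3)
and closing does not restore them.

CA is the count of set pixels of the smoothed mask (px²; no mm²
conversion — scan geometry is device-specific and out of scope).  COID is
the arithmetic mean of the **original** image over the smoothed mask: the
sharpened image exists for boundary detection, while optical density
should reflect the raw signal (`coid_on_sharpened` preserves the
alternative).  COID of an empty mask is an explicit error, never a silent
NaN or 0.

## Statistics

All implemented from formulas; `scipy.stats` appears only as a test
oracle.

* **Student's t**: pooled-variance by default (the variant classic
  statistical packages label "Student's"); Welch by flag.  Two-sided p via
  the regularized incomplete beta, `p = I_{ν/(ν+t²)}(ν/2, 1/2)`.
* **KS normality**: `D = sup|F_n − Φ((x−x̄)/s)|` with sample-estimated
  parameters.  Because estimation makes the naive KS p anti-conservative,
  p is calibrated by seeded parametric resampling (Lilliefors; default
  2,000 replicates, null distribution cached per sample size).
* **Pearson r** with `t = r·sqrt((n−2)/(1−r²))`.
* **CoV**: per subject `100·SD/mean` (n−1 denominator), averaged across
  subjects.
* **ICC(2,1)**: two-way random effects, absolute agreement, single
  measure — `(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))` — the form
  that treats examiners as a random rater sample; the ANOVA mean squares
  are returned for audit.  Inter-observer analysis uses examiners as
  raters; intra-observer uses one examiner's repeated sessions.

All p-values are two-sided; no multiple-testing correction is applied
(none is part of the analysis being reproduced).

## Synthetic phantoms

The generator emulates the gross layered appearance of a macular B-scan:
dark vitreous; a bright retinal complex (default 180) ending in a brighter
RPE-like line (+40, ≈ 0.8 % of image height thick); a choroid band of
stated thickness at stromal intensity (default 110) carrying elliptical
vessel lumens (default intensity 40, target fraction 0.25, semi-axes
10–22 % of band thickness so each lumen adds 1–2 % of band area); darker
sclera below (default 15, same as vitreous).  Layer boundaries undulate as
a two-term random-phase sinusoid (amplitude 8 px at full scale); the band
has constant integer thickness per column, so the true band area is
exactly `thickness × width`.  Speckle is the L-look multiplicative model:
each pixel times `g ~ Gamma(L, 1/L)` (mean 1, variance 1/L; default
L = 6), then clamped to [0, 255].  Clamping slightly biases means near the
scale ends; defaults keep band intensities well inside [30, 200], where
the bias is negligible.  Geometry defaults are stated at 992 × 1024 and
scale linearly via `PhantomParams.scaled`.

Each phantom carries its truth: the exact band mask, its area, and the
expected pre-speckle band mean `(1−f)·stroma + f·lumen` with f the
realized lumen fraction.  Cohorts jitter per-subject thickness (SD = 8 %
of the group mean by default) and stromal intensity (SD = 4), with each
subject's seed derived from its jittered parameters so that zero jitter
reproduces identical phantoms.  The diabetic group defaults to a 40 %
thinner, 25-units-brighter choroid — qualitatively matching the direction
and roughly the relative separation of the published group summaries.

What the phantoms do **not** model: foveal pit geometry, depth-dependent
signal roll-off, vessel shadowing, motion artifacts, pathology lesions, or
physically accurate wave-optics speckle correlation.  Passing recovery
tests therefore demonstrates the pipeline's correctness and stability
under known geometry and heavy multiplicative noise — not clinical
accuracy on real scans.

## Validation problem sizes and operator settings

The test suite validates morphology against a brute-force Minkowski oracle
on masks up to 64 × 64 (r ∈ {0, 1, 2, 3, 5}), SLIC partition validity and
cross-implementation agreement on twenty 256 × 248 phantoms, and
truth-guided recovery on twenty 512 × 496 phantoms, where the pipeline is
run with `K = 600`, `m = 60`, `r = 2` — the operator-chosen ("specialist")
settings for that phantom geometry, sized to a superpixel diameter of
about one fifth of the band thickness.  Under those conditions the median
CA recovery error is a few percent (boundary ambiguity under speckle is
the dominant term: stromal pixels at the band edge fluctuate into
sclera-like values far more often than the reverse, so the segmented band
is biased slightly inward) and COID recovery is well within one intensity
unit.  Group-comparison significance checks simulate cohorts directly from
the published summary statistics (n = 110 vs 92), and statistical
calibration checks use 2,000 null repetitions (type-I error of the pooled
t) and 100 repetitions of the Lilliefors-calibrated KS on n = 10,000
normal samples.

## Known limitations

* The method is semi-automatic by design: without a selection input there
  is no segmentation.  `auto_select` reproduces a given reference; it does
  not find the choroid on its own.
* CA is reported in px² only.
* The SLIC implementation is plain (no SLICO/adaptive compactness, no
  multichannel support) and prioritizes clarity and determinism over
  speed; full-scale 1024 × 992 scans take tens of seconds per image in
  pure numpy.
* The Lilliefors null distribution is cached per (n, replicates, seed);
  very large samples with many distinct sizes will regenerate it each
  time.
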