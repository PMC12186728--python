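# Methods

`punctakit` quantifies intranuclear protein-aggregate puncta in
multi-channel fluorescence microscopy. The motivating biology is the
nuclear aggregation of PABPN1 in muscle cells: the benign wild-type
protein (10-alanine stretch) forms few, small, round, slowly remodelling
nuclear puncta, while the disease-associated expanded variant (16
alanines, the OPMD mutation) forms more numerous, larger, irregular,
faster-moving aggregates that co-sequester polyadenylated mRNA. The
package implements the image-quantification side of that comparison as a
reusable, tested pipeline, together with a synthetic-scene generator that
makes every stage verifiable against known ground truth.

## Segmentation model

**Nuclei.** The counterstain channel is Gaussian-smoothed (default sigma
2 px), thresholded by Otsu's method, hole-filled, and optionally split by
a distance-transform watershed (markers = distance peaks at least 2 um
apart). Each nucleus gets a perinuclear ring of configurable width
(default 2 um) built with nearest-nucleus label expansion, so rings of
neighbouring nuclei are disjoint by construction and serve as a
per-nucleus cytoplasmic proxy. Nuclei touching the image border are
flagged and excluded from summaries by default, because truncation biases
area and circularity. A constant (blank) channel yields an empty ROI list
with a warning, not an exception.

**Puncta.** The aggregate channel is masked by a fixed recipe: Gaussian
blur (default sigma 1.5 px; 1.0 px for the mRNA channel), optional
despeckle — defined as a 3x3 median filter, the standard meaning of that
operation in interactive image analysis — binarization at a *constant*
raw-intensity threshold, 8-connected components, and a strict area filter
(area > 0.01 um^2 by default; "strict" means a particle of exactly the
cutoff area is discarded). Mean fluorescence intensity (MFI) is always
measured on the raw, un-blurred pixels under the mask; the blur exists
only to build the mask, which keeps intensities comparable across sigma
choices. This is a documented assumption: measuring on smoothed data
would systematically shrink punctum MFI as sigma grows.

Puncta are assigned to the nucleus containing their centroid; a punctum
whose centroid falls outside every nucleus is assigned to the nucleus
with the largest mask overlap, or flagged extranuclear. Thresholds are
echoed per call to the run manifest so the constant-threshold contract
across a batch is auditable.

**Dual-threshold profile.** Two constant thresholds applied to the same
blurred image quantify, per nucleus, bulk signal (low threshold) versus
aggregated signal (high threshold): `aggregation_index` = total intensity
in the high mask / total intensity in the low mask, in [0, 1]. Because
both masks binarize the same processed image, the high mask is nested in
the low mask pixelwise, and dropping sub-cutoff components cannot break
the nesting (a dropped low component can only contain an even smaller
high component). Thresholds are per-experiment configuration: instruments
and acquisition settings put them on different scales, so no default pair
is meaningful beyond the shipped synthetic calibration (120 / 650).

## Morphometrics

Circularity is 4*pi*A/P^2 with the 4-direction Crofton perimeter
estimator, clamped at 1 — small rasterized disks overshoot 1 with any
discrete estimator (a radius-2 px disk measures ~1.08 before clamping; a
radius-10 px disk measures 0.98). Intranuclear variability is the sample
standard deviation (ddof = 1), with the coefficient of variation behind a
flag, since "variability" does not pin down a statistic. The
area-circularity relationship is an ordinary least squares fit of
log2(circularity) on log2(area); direction (circularity as response) is a
documented choice, and both the slope and the Pearson correlation of the
two log2 variables are reported so the choice is auditable. The F-test of
zero slope requires n >= 3 and non-degenerate log2(area).

The punctate/bouquet classifier is a rule-based analog of manual
morphology scoring: a nucleus is "bouquet" if any punctum exceeds the
area threshold (default 1.0 um^2) AND is either non-circular (< 0.8) or
multi-lobed (>= 3 lobes), "punctate" if it has puncta but none meets the
rule, "none" otherwise. Lobes are counted as local maxima of the
intra-blob Euclidean distance transform separated by >= 2 px — the
simplest reproducible surrogate for "connected punctate units". The
defaults were fixed from the generator's blob geometry before the
pipeline was assembled.

## Overlap dynamics

Puncta mobility is quantified without tracking: three frames of a
time-lapse are binarized with the same constant-threshold recipe, and per
nucleus the "white" area (triple intersection) is divided by the
"colored" area, interpreted as the triple union — a Jaccard-style
statistic in [0, 1] that is exactly 1 for immobile puncta and symmetric
under frame permutation. The alternative reading of "colored" as
union-minus-intersection is available via a flag (it is unbounded above
as overlap grows, which is why union is the default). The frame-time
default is configurable; analyses here use three consecutive frames 2 s
apart, which is the regime where the statistic is informative for
diffusion coefficients around 0.001–0.2 um^2/s given ~0.3–0.9 um puncta.
Comparisons between conditions should be restricted to nuclei of similar
bulk intensity (the low-threshold MFI is reported per nucleus for that
gating).

## Colocalization, compartment ratio, texture

Manders coefficients follow the co-occurrence convention: M1 = sum of
channel-A intensity over the intersection of both masks / sum over the
A-mask, M2 symmetrically. Sums use background-subtracted intensities
(clipped at zero) when a background estimate is supplied; the pipeline
estimates background per channel as the median intensity outside all
nuclei and rings. Without subtraction a constant camera offset dilutes
the coefficients toward the mask-area ratio. Pearson correlation is
computed over all nucleus pixels by default (the common plugin default),
with a mask-restricted option; it is offset-invariant, so no subtraction
applies. The overlap area in um^2 is also emitted, since "signal
overlap" can reasonably mean M1, M2 or area — all three are reported.

The compartment ratio is log2(nuclear MFI / perinuclear-ring MFI), null
when the ring is empty (border nuclei) or the denominator is zero.

Texture descriptors come from a gray-level co-occurrence matrix computed
inside the (non-rectangular) nucleus mask: per-ROI min-max quantization
to `n_levels` (256 emulates 8-bit conversion), pair counting at a fixed
offset (default (0, 1), i.e. distance 1 at 0 degrees; the four standard
directions can be averaged), symmetrization, normalization. Entropy is
-sum p log p with natural log by default — the base is configuration and
a pure constant factor — and IDM is sum p_ij / (1 + (i-j)^2). The GLCM is
computed directly with numpy because library routines assume rectangular
inputs without mask support; a unit test cross-checks it against an
independent library implementation on rectangular regions. Note that
per-ROI min-max quantization makes the statistics invariant to the
absolute noise amplitude on an otherwise flat region (the range is
stretched before binning); a fixed `intensity_range` pins the scale when
absolute-amplitude sensitivity is wanted, and the noise-monotonicity
property (entropy rises, IDM falls with noise SD) is tested in that mode.

## Synthetic scenes and ground truth

The generator is first-class, tested code; it defines the conditions
under which the pipeline's guarantees are demonstrated.

* **Nuclei** are non-overlapping ellipses with random orientation,
  semi-axes 4.0–4.6 x 3.3–3.9 um (~8–9 um myonucleus-like diameters),
  placed by rejection sampling (a placement that cannot satisfy the
  non-overlap constraint raises a geometry error).
* **Puncta** are unions of 1..k offset disks. One disk gives a
  near-circular punctum; extra lobes (offset 0.9–1.5 radii, radius
  0.5–0.8 of the base) give "bouquet"-like irregular blobs with
  controllably reduced circularity. Per-punctum ground truth records the
  exact rasterized pixel area, the circularity of the noiseless binary
  blob (same estimator as the morphometrics module), the sampled peak
  intensity and the rendered plateau value (peak + background).
* **Mobility** is Brownian: per-frame Gaussian displacements with
  per-axis variance 2 D dt, radially reflected at the (margin-shrunk)
  nucleus boundary so blobs stay fully intranuclear.
* **mRNA channel**: per nucleus, a fraction f of the probe intensity
  budget is uniform over that nucleus's puncta and the remainder is
  diffuse, split between nucleus interior and perinuclear ring by a
  cytoplasm fraction (default 0.3; 0 models full nuclear retention). The
  diffuse term pervades punctum pixels too (soluble mRNA), so the
  realized punctum share slightly exceeds f; the realized value is
  recorded per nucleus.
* **Noise** is optional Poisson on the signal followed by additive
  Gaussian (default sd 4), each independently switchable so oracle tests
  can run noise-free. `edge_sigma_px` (default 0.5) smooths punctum
  edges; at 0 the rendering is crisply binary, which is what makes exact
  pixel-area recovery a meaningful test.
* **Determinism**: one integer seed drives a single explicit
  `numpy.random.Generator`; identical seed + parameters give
  bit-identical scenes.

Two documented presets encode the phenotypes: `ala10` (3 nuclei, Poisson
mean 3 puncta/nucleus, radius 0.32 +/- 0.06 um, single-lobe, peak 500 +/-
60, D = 0.005 um^2/s, mRNA coloc fraction 0.25) and `ala16` (mean 7
puncta/nucleus, radius 0.38 +/- 0.10 um, 2–5 lobes, peak 950 +/- 120,
D = 0.04 um^2/s, coloc fraction 0.60). The absolute scales are
calibration choices — no reference size or intensity distributions exist
for the real specimens — chosen so that the two presets differ in the
directions the biology dictates while remaining resolvable at 0.1 um/px.
What the generator does **not** emulate: optical point-spread functions
and sectioning, photobleaching, spatially varying background, nuclear
substructure (nucleoli), and cell crowding/contact. Passing tests
therefore demonstrate correctness of the measurement code under
controlled conditions, not robustness to every property of real images.

## Statistics

Group comparisons run on per-nucleus values by default (a per-scene
aggregation unit is available): two-sided unpaired Student t-test for two
groups, one-way ANOVA for more. Descriptives are always reported; the
test is withheld when any group has fewer than two values. No
multiple-testing correction is applied by default; a Benjamini-Hochberg
helper exists for batched comparisons.

## Numerical choices and degenerate inputs

* Areas are pixel counts x pixel_size^2; the strict area filter uses a
  1e-9 relative guard so "exactly the cutoff" lands on the excluded side
  despite floating-point products.
* Circularity is clamped at 1; MFI is measured on raw intensities.
* 16-bit inputs are analyzed at native depth; only texture quantizes.
* Empty masks, blank channels, empty rings, zero-variance fits and empty
  low-threshold masks all produce nulls-with-logging or typed errors, as
  documented per function, never silent wrong numbers.
* Result CSVs are written with 17 significant digits and re-read with
  round-trip float parsing, so write-then-read is the identity.

## Problem sizes used in validation

The shipped validation (test suite and `scripts/acceptance.py`) uses
288 x 288 px scenes at 0.1 um/px with 3 nuclei per scene: 10 scenes per
phenotype for the end-to-end discrimination (about 30 analyzable nuclei
per group), 10 seeds per diffusion level for the dynamics profile, 5
coloc fractions x 3 nuclei for Manders recovery, 100 random images for
the labeling oracle, and 200 repetitions of a 2-scenes-per-group
same-preset comparison for type-I calibration. These sizes give stable
statistics while keeping a full validation run around a minute on one
CPU.

## Known limitations

* The punctate/bouquet classifier is an analog of manual nanoscale
  morphology scoring, not a reimplementation of it; its thresholds are
  generator-calibrated defaults.
* The overlap-dynamics statistic measures mask turnover, not single
  particle motion; it saturates at 0 once displacement per interval
  exceeds the punctum diameter.
* Manders recovery carries a small positive bias from diffuse signal
  inside punctum pixels, bounded by the punctum area fraction of the
  nucleus (< 0.03 under the benchmark settings).
* The per-ROI min-max GLCM quantization is scale-free by design; use
  `intensity_range` for cross-condition comparisons of absolute
  heterogeneity.
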