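# Methods

`plateseg` quantifies platelet spreading from fluorescence microscopy
(typically an F-actin label) in five stages, each usable on its own. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic validation does and does not establish.

## Focus-aware projection

Stacks are reduced to 2D by finding the sharpest slice with Vollath's F4
autocorrelation measure,

    F4 = Σ_{x,y} I(x,y) I(x+1,y) − Σ_{x,y} I(x,y) I(x+2,y),

and taking the pixel-wise maximum over that slice ± 2 neighbours (five
slices for an interior focus). F4 peaks at best focus because defocus blur
suppresses the lag-1 autocorrelation faster than the lag-2 term.

Choices: the correlation runs along the first (row) axis only — the metric
is near-isotropic and a fixed axis keeps results reproducible. Intensities
enter unnormalised, since the argmax is invariant to positive global
scaling. Ties break to the lowest slice index. At stack edges the window is
clipped rather than erroring, so a focus at slice 0 uses three slices. A
single-plane image passes through unchanged.

## Pixel classification

Segmentation follows the interactive-learning idiom: sparse user scribbles
(signal / background) on a handful of training images, a multi-scale
feature bank, and a random forest.

* Scales: σ ∈ {0.7, 1.0, 1.6, 3.5, 5.0, 10.0} px.
* Kinds: Gaussian-smoothed intensity, gradient magnitude, Laplacian of
  Gaussian, difference of Gaussians (σ vs 1.6σ), structure-tensor
  eigenvalues (2 planes), Hessian eigenvalues (2 planes) — 8 planes per
  scale, 48 features per pixel.
* Forest: 100 trees, unlimited depth, seeded; single-threaded for
  determinism.
* All filters use reflect boundary handling.

The signal probability map is thresholded at 0.5 (the two-class argmax
rule), holes are filled, and components under 50 px are removed to
suppress speckle. Both thresholds are configurable; 50 px is ~0.5 µm² at
the default 0.1 µm/px sampling, far below a resting platelet (~7 µm²), so
no real cell is at risk.

A fully automated baseline (Gaussian smooth at σ=1, global Otsu threshold,
hole filling, same size filter) is provided for comparison. It requires no
training but cannot adapt to local contrast.

## Separation of touching platelets

Platelets are anucleate, so nucleus-seeded splitting is unavailable; the
protocol is deliberately semi-automated. The user supplies one point per
member of every touching clump (from any point-picking tool, as a CSV).
Each connected component holding ≥ 2 seeds is split by a
marker-controlled watershed on the negated Euclidean distance transform of
the mask — "filling" the binary shape from the clicked centres, which
splits blobby objects at their necks and is insensitive to staining
heterogeneity (an intensity-relief watershed would not be). Components
with 0 or 1 seeds are kept whole: unclicked clumps are never split
silently. Seeds are dilated to 3×3 markers (clipped to the mask) so a
click landing on a thin structure still seeds a region. 8-connectivity is
used throughout; final labels are renumbered 1..N by (min row, min col)
so outputs are deterministic.

`validate_seeds` pre-checks a click pass: seeds off the mask or
duplicated, and unseeded components larger than 1.5× the 75th percentile
of component areas (candidate forgotten clumps). Both factors are
configurable; the default flags a two-platelet clump among typical
singletons while tolerating large fully spread cells.

## Morphometry

One record per label: area (px and µm²), perimeter, circularity
4πA/P² (clamped to ≤ 1), convex area, solidity, eccentricity, axis
lengths, extent, aspect ratio, centroid.

The perimeter is the total length of the marching-squares half-level
contour of the object (holes included), computed sub-pixel. This choice is
deliberate: boundary-pixel counting and Crofton-style estimators both
mis-calibrate circularity on small digital shapes (a 10×10 digital square
comes out at 0.93–0.97 instead of the continuous π/4 ≈ 0.785; the contour
estimator gives 0.83, and a radius-50 digital disk gives 0.91). The
aspect ratio floors the minor axis at one pixel so degenerate thin objects
stay finite. Objects touching the image border are flagged and excluded
from summaries by default, since truncation biases area.

## Object classification

A second random forest (100 trees, seeded) maps per-object shape features
to three morphology classes: unspread, partially spread, fully spread.
Intensity features are deliberately excluded so the classifier transfers
across stains and imaging modalities; forests are scale-invariant so no
feature standardisation is applied.

Validation reserves a stratified 20% hold-out (per-class nearest-integer
shares, remainder to the largest class), reports a confusion matrix and
overall accuracy, and runs a feature ablation over four arms — {area},
{circularity}, {area, circularity}, all features — on one shared split so
the arms are directly comparable. Manually chosen thresholds on area or
circularity alone are avoided; the ablation quantifies exactly how much
accuracy such single-feature rules give up.

## Replicate statistics

The statistical unit is the biological replicate: platelets from one
coverslip are not independent, and treating them as such would
pseudo-replicate. Each (condition, replicate) is reduced to its mean area,
mean circularity and class percentages; conditions are compared by one-way
ANOVA on the replicate values followed by all pairwise two-sample t-tests
with Bonferroni correction over the number of condition pairs (per metric,
not across metrics). Pooled-variance t-tests are the default, consistent
with the ANOVA's equal-variance assumption; `equal_var=False` switches to
Welch.

## Synthetic validation data

The generator builds ground-truthed scenes so every stage can be scored
without real microscopy:

* **unspread** — near-circular disks, radius 1–2 µm (resting platelets are
  2–4 µm discoid cells), radial noise 2–6%;
* **partially spread** — disks of radius 1.2–2.2 µm with 3–8 thin
  (3 px ≈ 0.3 µm) filopodia of 0.8–2 µm;
* **fully spread** — low-order Fourier-perturbed blobs of radius
  2.5–4 µm (up to ~8 µm across), amplitude 10–25%.

Defaults: 0.1 µm/px sampling, 512×512 fields, 30 cells. These parameter
ranges are chosen to preserve the *orderings* that make the analysis
meaningful — median area spread > partial > unspread, median circularity
unspread > partial — not any absolute values, which the source assays do
not constrain. Touching clusters place members with centre distance below
the sum of radii and assign contested pixels to the nearest member
centre, giving an exact ground-truth split for watershed scoring; one
interior seed per member (the point of maximal distance to the member's
boundary) plays the role of the user's click. Rendering converts the
label image to foreground 200 / background 10 intensity units, emulates
defocus with Gaussian blur of σ = 1 + 1·|i − focus| per slice, and adds
Gaussian noise (σ = 5 by default, ~3% of contrast). Placement retries are
capped at 100 per object; an infeasible scene errors with the number
placed.

Truth-derived scribbles sample signal pixels from the 1-px-eroded
foreground and background pixels from outside the 1-px-dilated foreground
(500 of each per image by default). The standoff is symmetric about the
object boundary; an asymmetric standoff measurably biases the forest's
learned boundary and costs ~2% IoU.

**What a green test establishes — and does not.** The synthetic world has
uniform foreground intensity, uniform background and purely additive
Gaussian noise; no per-cell brightness variation, no uneven illumination,
no autofluorescent debris, no optical PSF. On such scenes a global Otsu
threshold on the smoothed image is near-optimal, so the trained pixel
classifier matches the baseline to within ~0.5% IoU at every noise level
tested (both ≈ 0.95 at 30% noise) instead of clearly exceeding it. The
advantage of learned segmentation on real data comes precisely from the
heterogeneity this generator omits; synthetic results validate the
machinery (features, training, thresholding, conservation, determinism),
not the real-data superiority claim. Likewise the object classifier's
near-perfect synthetic accuracy reflects the generator's well-separated
class geometry, not expected performance on manually annotated platelets.

## Known limitations

* Pixel features and the baseline assume 2D images; no 3D segmentation.
* The watershed split is only as good as the user's clicks; a missed click
  leaves a clump as one object (by design), inflating area summaries —
  `validate_seeds` exists to catch this.
* Circularity of objects under ~50 px² is dominated by digitization and
  should not be over-interpreted.
* Class annotations supplied against a different labelling (e.g. a manual
  layer) transfer to the pipeline's segmentation by majority pixel
  overlap with a ≥ 50% threshold; heavily over- or under-segmented
  objects lose their annotation rather than inheriting a wrong one.
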