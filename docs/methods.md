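# Methods

This note documents the models, conventions and numerical choices behind
`octdme`, and what the phantom-based tests do and do not demonstrate.

## Coordinate and intensity conventions

B-scans are 2-D arrays with depth along rows (row 0 on the vitreous
side) and the lateral dimension along columns; coordinates are 0-based
with half-open ranges. All processing happens in floating point scaled
to [0, 1]; quantization to 8-bit happens only when volumes are written
to disk, with round-half-even. Border handling is reflect (half-sample
symmetric) throughout.

## Speckle model

Fully developed speckle is modeled multiplicatively: each pixel of the
clean image is multiplied by an i.i.d. gamma variate with shape L
("looks") and mean 1, so the clean image is preserved in expectation and
the relative noise variance is 1/L. L = 4 is used where strong noise is
wanted (denoiser benchmarks), L = 16 for classification experiments.
The model captures the signal-dependent, non-Gaussian character of OCT
speckle but none of its spatial correlation.

## Denoising

Implemented from their defining formulas: mean and median filters (odd
windows ≥ 3), the Lee local-statistics filter
(out = m + k·(img − m), k = max(0, v − σ²)/v with σ² estimated as the
image mean of local variances), wavelet hard/soft shrinkage of detail
subbands (db2, 2 levels; when no threshold is given, the universal
threshold σ̂·√(2 ln N) with σ̂ from the MAD of the finest diagonal
subband), and non-local means with weights
w(i,j) = exp(−‖patch_i − patch_j‖²/h²) over an s × s search window,
vectorized over search offsets with box filters. Patch-based and
transform-domain methods beyond these (BM3D and relatives) are
deliberately out of scope; a plug-in hook accepts any image → image
callable. NLM (patch 5, search 11, h = 0.6 on [0, 1] data) is the
pipeline default; h was chosen once so that NLM clearly improves PSNR on
speckled phantoms at L ∈ {4, 16} while preserving lesion boundaries.
PSNR is 10·log₁₀(peak²/MSE) with peak defaulting to the declared
intensity maximum.

## RPE localization, flattening, cropping

Candidates: per column, the argmax of the depth profile smoothed with a
Gaussian of σ = 3 px; columns whose maximum is below 10% of the image
maximum are treated as missing. A quadratic row(x) = a·x² + b·x + c is
fitted by RANSAC (500 iterations, inlier tolerance 3 rows, minimal
3-point samples, ties broken by lower inlier squared error, final
least-squares refit on the best consensus set; deterministic given a
seed). Flattening shifts each column by the integer
round(max model) − round(model(x)) so the RPE lies on the deepest
predicted row, filling vacated pixels with 0; integer shifts (no
interpolation) preserve LBP patterns. The crop spans 325 rows above and
30 below the flattened RPE row inclusive (356 rows) and a centered
340-column strip (left edge floor((cols − 340)/2)); windows extending
past the image are zero-padded and logged. The 356-row height is the
choice consistent with the canonical per-level HoG sizes.

## Descriptors

A 4-level Gaussian pyramid smooths with the separable binomial kernel
[1,4,6,4,1]/16 and keeps even-indexed rows/columns truncated to
floor-halved dimensions, so level k has dims floor(d/2^(k−1)) — the only
reading consistent with all four per-level HoG sizes.

**LBP.** P neighbors on a radius-R circle (angles 2πk/P, dr = −R sin,
dc = R cos rounded to 1e−5, bilinear interpolation, exact grid values
for integral offsets) are compared to the center with ≥ (ties count 1).
riu2 maps uniform codes (≤ 2 circular transitions) to their popcount and
all others to P+1 (P+2 labels); u2 keeps uniform codes distinct
(P(P−1)+3 labels). The width-R border is excluded from histograms.
Histograms are computed per patch and L1-normalized. The default patch
partition is a per-level grid of 3×3 / 2×2 / 2×2 / 1×1 = 18 patches,
the only layout that reproduces the canonical LBP descriptor lengths
(18 × {10, 18, 26} = 180/324/468); a literal 32-px tiling mode is
available behind `patch_mode="tiles32"`. Leftover pixels from floor
division are merged into the last patch.

**HoG.** Central differences with edge-replicated borders; unsigned
orientation in [0°, 180°) binned into 9 bins with magnitude-weighted
linear interpolation between adjacent bins (circular wrap); 4 × 4 px
cells (trailing pixels dropped); 2 × 2-cell blocks at 1-cell stride with
L2 normalization v/√(‖v‖² + ε²), ε = 1e−5, no clipping. Per-level
length is (cells_r − 1)(cells_c − 1)·36.

`descriptor_length` gives every length in closed form and is asserted
against the extracted vectors.

## Representations and classification

Histogram: the concatenated per-B-scan histograms. Histogram+PCA:
PCA with 40 components for HoG and 20 for LBP, component signs fixed
(largest-magnitude loading positive) for determinism; at desk scale the
component count is clamped to n_train − 1 with a logged warning.
Histogram+PCA+BoW: a k-means codebook (k-means++ init, 10 restarts, tol
1e−6, max 300 iterations) over PCA-reduced training B-scan vectors;
each volume becomes the occurrence histogram of nearest-word assignments
(ties to the lowest index), whose counts sum to the volume's B-scan
count.

Classifiers: linear SVM (C = 1), RBF SVM (C = 1, γ = 1/dim), random
forest (100 trees, unlimited depth). Features are standardized with
training-fold statistics before SVMs (not before the forest). B-scans
inherit their volume's label for training, since ground truth exists
only per volume; this injects label noise on lesion-free B-scans of
diseased volumes, which the majority vote at test time absorbs. The
vote declares DME when the diseased count is at least n/2 — exact ties
go to DME, favoring sensitivity in a screening setting.

Cross-validation is leave-two-patients-out: the i-th DME and i-th
normal patient (manifest order) form fold i; PCA, the codebook and the
classifier are fitted per fold on training patients only. Reports
accumulate volume-level confusion counts over all folds.

## Phantom generator

The phantom emulates the statistical structure the descriptors consume,
not OCT physics (no attenuation, PSF or shadowing). A dark vitreous
overlies four piecewise-constant retinal bands whose offsets are fixed
fractions of the image height; the RPE band is centered on a quadratic
curve and carries a 10% intensity taper toward its edges so the
per-column brightest pixel and the smoothed-profile detector agree on
the curve row; a moderately reflective choroid (0.45) lies below,
keeping the detector unbiased. Per-volume randomness is the RPE
curvature (vertex depth 0.45–0.65 of height, sag 2–7%); band intensities
are jittered per scan (±0.05) as acquisition variability. DME B-scans
carry a lesion complex reflecting clinical presentation — one
thickening bulge (30–60% of retinal thickness), 2–4 intraretinal
cystoid ellipses (10–30% of retinal thickness) and, with probability
0.3, a subretinal fluid pocket — all darkening or displacing tissue by
the configured contrast; draws violating the geometry invariants are
rejected. DME volumes place lesions on a random 60–85% of their
B-scans (the floor guarantees a correct majority vote is attainable);
normal volumes are lesion-free.

Passing phantom tests therefore show that the pipeline's geometry,
estimators and protocol behave correctly and that lesion-driven texture
differences are recovered end to end; they say nothing about
performance on clinical scans, whose anatomy, artifacts and lesion
textures are far richer.

## Problem sizes and determinism

Tests run at desk scale: 256 × 512 phantoms for the classification
experiment (8 + 8 volumes, 32 B-scans each), 448 × 512 where the full
356 × 340 crop must fit without padding, and ≤ 16 × 16 images for
brute-force oracle comparisons. Every stochastic component (speckle,
lesion sampling, RANSAC, PCA, k-means, classifiers) draws from an
explicit seed; identical seeds give identical outputs, including
byte-identical simulated datasets.

## Known limitations

- The phantom's layered-band texture is far simpler than real retinal
  texture; absolute SE/SP on phantoms do not transfer to clinical data.
- The RPE detector assumes the RPE is the brightest depth-smoothed
  structure; severe shadowing or detachments would violate this.
- Only the RPE is localized; no multi-layer segmentation.
- Flattening uses integer shifts; sub-pixel alignment is deliberately
  not attempted.
- The 18-patch LBP partition is a reverse-engineered layout matching
  the canonical descriptor sizes; the original patch layout is not
  recoverable from its description.
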