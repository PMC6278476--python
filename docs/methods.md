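# Methods

## Measurement model

A line-scan NIR hyperspectral camera records a cube `I(x, y, λ)` of digital
numbers over 256 bands spanning 874–1734 nm (band centers modeled as a
uniform grid, spacing ≈3.37 nm). Radiometric calibration uses a white
reference (near-100 % reflectance tile) and a dark frame (shutter closed):

    R = (I_raw − I_dark) / (I_white − I_dark)

computed elementwise in float64 and clipped to [0, 1]. Cells where
`I_white == I_dark` (dead pixels) are set to 0 with a warning instead of
propagating NaN, so region averages stay finite. References may be full
cubes or single-line frames broadcast over scan lines (common for line-scan
systems, where the reference is acquired per column and band). The
correction is invariant to common affine rescaling of the three inputs and
monotone in the raw value — both are asserted as tests.

## Segmentation

Samples are bright against the near-black belt. The band image nearest
1119 nm (ties to the lower band index) is thresholded; Otsu's criterion is
the default because the histogram is strongly bimodal, and a fixed threshold
remains available. A constant image has no Otsu threshold and is rejected as
degenerate. The binary mask is cleaned by a morphological opening with a
disk of radius 1 and removal of components below 20 px — enough to kill
sensor specks without eroding flower heads at radii of 6 px and up — and
labeled with 8-connectivity (thin petal bridges must not split a sample).
Labels are remapped to the raster-scan order of each component's first
pixel so region ids are reproducible across labeling backends. The mask from
the 1119 nm band is applied unchanged to every other band.

## Spectral preprocessing

Line-scan systems are unstable at the spectral extremes, so only a
contiguous run of 200 of the 256 bands is analyzed. The run is defined by
band count, anchored at the band nearest 975 nm, which on the default grid
retains indices 30–229 (centers ≈975.2–1646.3 nm). Defining the crop as an
index run keeps the retained count grid-exact; the range is recorded in the
output metadata.

Pixel spectra are smoothed by a wavelet low-pass: Daubechies-6
decomposition to level 3, detail coefficients zeroed, reconstruction.
Zeroing (rather than soft-thresholding) keeps the operator linear, which
makes per-pixel smoothing commute with region averaging and makes the
operator a projection. The signal-extension mode is periodization: for an
orthogonal wavelet this makes the low-pass an exact orthogonal projection —
idempotent to machine precision and strictly variance-reducing on noise —
whereas symmetric padding re-applies with ~1e-3 drift. Symmetric padding
remains available as a parameter. Level 3 on 200 bands requires length
≥ 88; shorter inputs are rejected.

Smoothing is applied pixel-wise *before* averaging; each segmented region
then contributes one unweighted mean spectrum. Tables carry integer variety
labels 1..K (for the seven reference varieties: 1 = Boju, 2 = Chuju,
3 = Gongju, 4 = Hangbaiju, 5 = white Huaiju, 6 = yellow Huaiju, 7 = Qiju).

The train/test split is stratified per class: `floor(n/4)` rows drawn
without replacement into the test set, the rest to training. This is the
allocation that reproduces the reference totals 8280/2758 from the
per-variety counts 1600, 1500, 1643, 1600, 1500, 1590, 1605. Union identity,
disjointness and the ≤25 % per-class test fraction are property-tested.

## Chemometrics

PCA is fit (mean-centered, full SVD) on pooled masked pixel spectra; the
sign convention makes each loading's largest-magnitude element positive so
score images are reproducible. A score image assigns each foreground pixel
`(spectrum − mean)·loading_k` and leaves the background exactly zero.

Second derivatives are Savitzky–Golay (window 9, polyorder 2 by default,
both configurable), scaled by the actual band spacing, so units are
reflectance·nm⁻²; edges use the truncated-window polynomial fit. The
window/polyorder defaults are the de-facto standard for NIR work; the
derivative algorithm behind commercial chemometrics packages is not
standardized, so the automatic selection is this package's own
formalization of "large differences between varieties": per band, the
between-class variance of the class-mean second derivatives, filtered to
local maxima of the score curve, ranked, and cut at `top_m`. The zero-signal
test is relative to the derivative scale (scores below `(1e-12·max|D|)²`
count as no signal) because second-derivative magnitudes are ~1e-4 nm⁻².
Automatic selection is invariant to class relabeling and to adding a common
constant to all spectra. Manual mode maps a requested wavelength list
(reference: the eighteen bands 999–1633 nm) to nearest grid bands, ties to
the lower index, rejecting wavelengths outside the grid span and collapsing
duplicates with a warning.

## Discriminant models

**SVM.** RBF kernel; penalty `c` and kernel width `g` searched on a
powers-of-ten grid (`c ∈ 10^{−2..8}`, `g ∈ 10^{−8..2}`) by stratified
cross-validation on the training set, best pair refit on all of it.
Features are z-scored with training statistics inside the pipeline — RBF
distances are scale-sensitive and reflectance bands share a scale only
approximately.

**Logistic regression.** One-vs-rest binary models, penalty L1 or L2,
inverse regularization `c′`, solver selectable among newton-cg, lbfgs,
liblinear, sag(a); invalid penalty/solver pairs are rejected up front.
Features are z-scored as for the SVM. Class = argmax of the normalized
per-class probabilities.

**1-D CNN.** Built and trained in NumPy (`network.py` implements the layer
set with explicit backprop; gradients were verified against central
differences to ~1e-8 relative error). Architecture: `num_convs` modules,
each two 1×3 convolutions (stride 1, padding 1) with
`num_first_kernels·2^(m−1)` filters — two stacked 3-wide kernels give a
5-wide receptive field at fewer parameters — batch normalization before
every ELU, then 1×2 max pooling with floor on odd lengths (25 → 12). After
flattening: a dense layer (`fc_hidden`, default 256) with BN + ELU, then the
output dense layer with neither, and a softmax. ELU's α defaults to 1.
Training minimizes mean cross-entropy by SGD with learning rate 0.001 and
momentum 0.9, batch size 256 (auto-shrunk with a warning if it exceeds the
training-set size), for a fixed `epoch` budget with no early stopping.
Weight init is He-style; init and shuffling derive from one seed, so
training is bit-reproducible. The network consumes reflectance directly —
batch normalization absorbs scale. For the reference 200-band architecture
(4 modules, 32 first kernels, fc 256, 7 classes) the parameter count is
1,182,119, asserted against a hand-computed sum.

Evaluation reports accuracy as exactly `trace(confusion)/total` together
with the full confusion matrix; a band-count mismatch between model and
table is an error rather than a silent re-projection.

## Classification maps

Prediction is per region on the mean spectrum (not per pixel): each
segmented sample is preprocessed exactly as the training data (crop →
pixel-wise smoothing → averaging → optional band selection), classified
once, and its label painted onto all of its pixels; background stays black.
The palette is a fixed colorblind-safe seven-color set (Okabe–Ito), and PNG
rendering is deterministic (two renders of the same map are byte-identical).
A JSON sidecar records region-id → predicted class.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes, not
the radiometry of a specific camera. Variety reflectance curves are a
gentle linear baseline (0.45 rising by 0.05 across the range) plus Gaussian
bumps at 1116 and 1308 nm (amplitudes ~0.10/0.08) and dips at 1200 and
1460 nm (~0.08/0.15), all 30 nm wide — the simplest smooth curve family
with the observed peak/valley placement. Classes share these positions and
differ by (a) a flat class offset on a uniform ladder (default step 0.05)
and (b) ~15 % class-specific perturbations of the bump/dip amplitudes. By
default classes 1 and 4 are placed a quarter-step apart so that one variety
pair is barely separable by level and must be separated by curve shape,
mimicking variety pairs whose mean spectra nearly coincide over part of the
range; the pair can be disabled for separability studies.

Within a scene, each sample disk receives a flat per-sample offset
(sd 0.005) plus i.i.d. per-pixel/band noise (sd 0.01), clipped to [0, 1].
The background is reflectance 0.02 (a black belt is not a perfect
absorber). Scenes are composed as `raw = dark + (white − dark)·R` with a
dark frame of mean 100 DN (sd 2) and a white frame 4000 DN above dark,
modulated by a smooth ±5 % quadratic illumination field across columns so
that reference correction is non-trivial yet exact. Raw values are clamped
between the references, which keeps corrected reflectance in [0, 1]. Disks
are placed by rejection sampling with a 2 px separation margin and bounded
retries (failure raises rather than silently overlapping). All randomness
fans out from one `SeedSequence`, so every public operation is
deterministic given its seed.

What the generator does **not** model: petal-level morphology and texture,
wavelength-dependent illumination color, detector nonlinearity and striping,
scattering artifacts, and chemistry-driven covariance between bands. Passing
tests therefore demonstrate the correctness of the processing chain and the
models' ability to recover planted class structure — not field performance
on instrument data.

## The end-to-end benchmark

The reference experiment (`benchmark.py`, also run by
`scripts/acceptance.py`) uses 7 classes × 80 samples (ten 300×300 scenes,
eight samples per class per scene, radii 6–10 px), uniform offset ladder
with step 0.05 = 5× the pixel noise sd and no near-overlap pair, so classes
are cleanly separable. The CNN benchmark configuration is 3 modules / 16
first kernels / 50 epochs / batch 64 / fc 64: batch 64 because the paper-
scale default of 256 would exceed the ~420 training spectra and give a
single update per epoch, and a three-module network because 560 samples do
not warrant a million-parameter model. The SVM search uses 3-fold CV at
this dataset size. Expected outcome (asserted in the acceptance test): all
three models ≥95 % test accuracy and 100 % of planted regions recovered by
segmentation (Jaccard > 0.9, one-to-one).

## Numerical and degenerate-input choices

* Division guard in calibration: 0 with warning, never NaN.
* Nearest-band lookups break ties toward the lower index everywhere.
* Requests outside the grid span warn (band image) or raise (manual band
  selection) depending on whether a nearest answer is still meaningful.
* Otsu on a constant image, empty wavelength grids, too-short spectra,
  unknown region ids, `k` beyond `min(n−1, B)` in PCA, invalid
  penalty/solver pairs, and pooling a sequence to length 0 all raise typed
  exceptions (`exceptions.py`) instead of returning sentinel values.
* Empty masks and empty scenes flow through: empty in, empty out.
* ENVI files are little-endian float32 or uint16; BIL/BSQ/BIP interleaves
  are supported for read and write, and a header/binary size mismatch is a
  format error.

## Known limitations

* The automatic wavelength selector is a formalization of a visual
  criterion; on real data its picks need not match an analyst's.
* The CNN trainer is single-threaded NumPy: adequate for hundreds to a few
  thousand spectra, not for million-sample studies.
* Watershed splitting of touching samples is out of scope; scenes are
  assumed to have separated samples.
* Reference frames must match the raw cube's grid exactly; no spectral
  resampling is performed.
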