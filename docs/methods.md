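# Methods

## Problem and pipeline

B-mode ultrasound renders tissue micro-structure as speckle: interference of
echoes from sub-resolution scatterers.  Diffuse liver disease changes the
speckle's second-order statistics — normal parenchyma shows fine, dense,
uniform grain; cirrhosis coarse, unevenly distributed echoes; hepatocellular
carcinoma irregular texture with a widened gray-level range and hypoechoic
lesions.  The package quantifies these differences with 30 texture features
per region of interest and classifies them with an RBF-SVM whose feature
subset and hyperparameters are selected by a clonal-selection immune
algorithm.

## Preprocessing

Images are 8-bit grayscale (RGB reduced with BT.601 luminance weights).  The
enhancement chain is: median filter (default 3×3 — the standard
edge-preserving despeckler; the kernel is configurable), then a
percentile-linear contrast stretch mapping the 1st/99th intensity
percentiles to 0/255 (outlier-resistant reading of "enlarge the gray
range"; histogram equalization is available behind a switch), then optional
Otsu binarization used only for visual QC.  ROI pairs are placed manually
(A1 lesion, A2 normal reference) and validated against three principles:
no overlap, row centers within `depth_tol` (default 10 px — the linear-probe
reading of "same depth"), and each rectangle large enough to hold one
1×1 cm analysis window.  Pixel spacing defaults to 0.1 mm so that window is
100×100 px.  Coordinates are 0-based, row-major, half-open.

## Texture features

Each ROI is tiled into non-overlapping 1×1 cm windows; the ROI feature
vector is the mean over windows.  The fixed 30-column layout is:

* **18 GLCM statistics.**  Intensities are quantized to 32 equal-width bins
  (GLCM size is O(levels²); 32 keeps small windows well populated).  Pair
  counting is symmetric (each ordered pair counted in both directions), and
  the raw pair count T is stored so the convention is auditable.  Offsets:
  d=1 at 0°/45°/90°/135° plus d=2 at 0°/90° — six offsets × entropy, ASM,
  contrast.  Which offsets beyond (1, 0°) the original protocol used is not
  recorded anywhere; this set covers all directions at the finest scale and
  the two axis directions at d=2, and fills the 30-feature budget.  Entropy
  is computed with the conventional minus sign and log base 2 (bits), so
  H ≥ 0 and a single-entry matrix has H = 0; ASM is the sum of squared
  entries (the plain sum of a normalized matrix is identically 1 and carries
  no information); contrast is the standard inertia Σ(i−j)²P(i,j).
* **3 Fourier ring energies.**  Centered power spectrum, DC removed,
  partitioned into equal-width concentric rings up to the Nyquist radius;
  per-ring energy normalized by total energy.  The standalone
  `fourier_ring_energies` defaults to 4 rings; the feature table uses 3 so
  the layout totals exactly 30 columns (18 + 3 + 9).
* **9 wavelet-fractal components** (below).

## Wavelet-fractal vector

A two-level hybrid decomposition: level 1 is a separable 2-channel Haar
split into LL/LH/HL/HH (LH = low-pass rows, high-pass columns); level 2
splits the LH band with a separable 3-channel orthonormal block transform
(filters proportional to [1,1,1], [1,0,−1], [1,−2,1]; a real-valued
uniform 3-band bank, chosen over a complex modulated bank so subbands stay
real).  The LH side is cropped to the largest multiple of 3 first (≤ 2
rows/columns lost).  The feature vector is

MF = (D_f of the raw window, D_f of LL, D_f of LH, D_f of six LH subbands),

where the six level-2 bands are the 3×3 subband grid minus the three bands
whose column filter is the low-pass, in raster order — the bands carrying
horizontal-detail and mixed structure of LH, which is where cirrhosis- and
carcinoma-like coarse texture differs most.  The exact band subset is a
reconstruction; the ordering is fixed and documented in code.

D_f is estimated by differential box counting (DBC): the grid is rescaled to
[0, 255] (so box-height quantization is consistent across subbands), tiled
by s×s blocks with box height s·256/side, the boxes needed to span each
block's min–max are summed into N(s), and D_f is the least-squares slope of
log N(s) against log(side/s) over s ∈ {2, 4, …, side/4} (at least two
scales), clipped to [2, 3].  A constant grid returns exactly 2.0.  Analysis
windows are center-cropped to 96×96 before decomposition (the largest
multiple of 8 in a 100-px window).

**Known limitation — DBC compresses the dimension scale.**  On a discrete
lattice, the per-block max−min of a rough Gaussian field undersamples the
continuum extremes at small block sizes (4 pixels cannot represent the
sub-pixel oscillations of a near-space-filling surface), so block ranges
grow faster than s^H at small s and the fitted slope falls short of 3−H.
The effect is intrinsic to box counting on sampled surfaces, strongest for
low Hurst exponents: on 256×256 spectrally synthesized fractional Brownian
surfaces (power spectrum ∝ f^−(2H+2), verified spectrally exact) the
estimator returns ≈ 2.38 / 2.23 / 2.09 for H = 0.2 / 0.5 / 0.8 (theory
2.8 / 2.5 / 2.2); an inclined plane returns 2.0.  D_f is therefore treated
as a monotone roughness index — strictly decreasing in H, shift-invariant,
deterministic — rather than an absolute dimension; that is all the
classifier needs.

## Immune optimizer

Antibody = 32 equal-width binary fields of n bits (default n=8, 256 bits):
fields 1–2 decode the SVM parameters, fields 3–32 the feature screens
(feature included iff its field decodes above the midpoint — equal-width
fields match the stated 32·n total length, unlike a 1-bit-per-feature
layout which would give 2n+30).  Field decoding maps bit patterns
bijectively onto a uniform 2^l-point grid of [d, u], the first bit least
significant.  C and r decode on log₂ scale over C ∈ [2⁻⁵, 2¹⁵],
r ∈ [2⁻¹⁵, 2³] — the standard RBF search box (bounds unstated in the
protocol).  An empty feature mask is repaired by switching one random
feature field fully on.

Affinity is the mean 5-fold cross-validated accuracy of the encoded SVM on
the masked columns, with per-training-fold standardization.  Identical
chromosomes are cached; the execution counter counts actual SVM trainings.

Each cycle: evaluate; clone the best antibody 30× and each other 10×
(population 5 — the study protocol); mutate clones only, by independent
per-bit flips at rate 1/n ("mutation probability inversely related to
coding length" operationalized as the reciprocal); per-lineage elitist
replacement (each parent survives unless one of its own clones is strictly
better), so the best affinity is monotone non-decreasing.  The loop stops at
a target affinity or the generation cap (protocol default 500).  Density
based suppression of similar antibodies — part of general immune-algorithm
descriptions — is not implemented: the concrete three-step procedure this
module operationalizes does not include it.

Convergence is reported both as best affinity (accuracy) and as the
objective 1 − best affinity; published convergence curves for this
algorithm family are drawn with "affinity" *decreasing* toward the optimum
even though affinity is defined as accuracy — an inconsistency we reproduce
in shape by plotting the objective, rather than resolve.

## Evaluation protocol and baselines

Five-group rotation: stratified 5-fold assignment; each fold tests a model
trained on the other four; overall accuracy is the mean of fold accuracies
and per-class accuracies are pooled.  Standardization and PCA are fitted on
training folds only (a dedicated test perturbs test folds and asserts the
fitted parameters are bit-identical).  Multi-class handling is one-vs-one.

Baselines: (a) exhaustive 15×15 log₂ (C, r) grid SVM on all 30 features over
the same search box as the optimizer, so execution counts are comparable;
(b) a plain clonal-selection classifier — class-tagged prototype vectors
(default one per class, initialized at the class centroid), refined by
cloning + annealed Gaussian mutation with affinity = negative mean distance
to the class's training samples, predicting by nearest prototype.  The
original comparison never specifies its standalone immune classifier; this
prototype classifier is our labeled stand-in, and with one prototype per
class it reduces to (a clonally polished) nearest-centroid rule;
(c) PCA+SVM with train-fold-fitted PCA (default 10 components).

## Synthetic data generator

Fully developed speckle: a complex circular-Gaussian scatterer field is
low-pass filtered at the class's correlation length (Gaussian σ, pixels) —
filtering preserves Gaussianity, so the envelope magnitude is exactly
Rayleigh-distributed at any grain size — then modulated by a slow
(σ = 48 px) multiplicative gain field scaled by the heterogeneity amplitude,
and mapped linearly onto the class gray range (99.9th-percentile top).
Default recipes encode the three sonographic axes with increasing
coarseness, heterogeneity, and gray range:

| class     | corr. length (px) | heterogeneity | gray range | lesion |
|-----------|-------------------|---------------|------------|--------|
| normal    | 1.0               | 0.05          | 20–200     | no     |
| cirrhosis | 2.2               | 0.35          | 10–225     | no     |
| cancer    | 2.6               | 0.45          | 0–255      | yes    |

The cancer lesion is an irregular hypoechoic blob (envelope × 0.45) covering
roughly a quarter of the frame.  Per-image parameter jitter (log-normal
σ = 0.12 on correlation length, 0.18 on heterogeneity, ±8 gray levels on the
range bounds) emulates biological variability: classes overlap but keep
their ordering on average, which makes the cohort learnable but not
trivially separable and makes cancer (whose texture parameters sit nearest
cirrhosis) the hardest class.  Default cohort: 100 images per class at
256×256 px, 0.1 mm spacing (four analysis windows per image), matching the
300-sample study design.  Images are preprocessed with the default chain
before feature extraction.

Note a consequence of speckle physics: *finer* speckle (normal) has the
*lower* ASM and higher entropy at d=1, because neighboring pixels
decorrelate; coarse speckle concentrates the GLCM near its diagonal.
Directional tests assert this physical ordering.

What the generator does **not** model: beamforming geometry, attenuation and
focal-zone depth dependence, scan-conversion interpolation of sector probes,
log-compression display curves, anatomical structures (vessels, ducts,
capsule).  Passing tests on this cohort demonstrate the pipeline's
correctness and the expected qualitative orderings, not clinical
performance on real scans.

## Problem sizes and numerical choices

The shipped study runs 100 images per class with the optimizer capped at 12
generations (early-stopped at affinity 0.99): with a population of 5 and
10×/30× cloning, that is already ≈ 4,000 SVM trainings and is past the
affinity plateau on this cohort; 500-generation behavior (elitism,
convergence) is exercised on an analytic surrogate affinity where
evaluations are free.  Tie-breaks: equal-affinity clones never replace their
parent (strict improvement required); `argmax` takes the first maximum.
GLCM normalization tolerance 1e-9; Fourier ring energies of a constant
window are defined as the zero vector; constant images are rejected by
binarization and returned unchanged by contrast stretch.
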