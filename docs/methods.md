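# Methods

This note records the conventions, defaults and open design choices
behind `histofusion`. Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Enhancement

Gray-world normalization scales each RGB channel by
`(mean of the three channel means) / (channel mean)` and clamps to
[0, 255]; a zero channel mean raises a degenerate-input error rather
than silently dividing. The enhancement stage then computes
`O = G_σ(I) − ∇²I` per channel in signed arithmetic before clamping.

* Gaussian: sampled isotropic 2-D kernel, σ = 1.0, 5×5, renormalized to
  sum exactly to 1. These defaults are a light denoise appropriate to
  the ~100× magnification scale of slide images; both are config keys
  (`sigma`, `kernel_size`).
* Laplacian: the 4-neighbor stencil `[[0,1,0],[1,−4,1],[0,1,0]]`,
  signed, unclamped. The 4-neighbor form is the literal discrete
  `∂²/∂x² + ∂²/∂y²`; the 8-neighbor variant was deliberately not used.
* Sign convention: smoothed minus Laplacian. The opposite reading
  (Laplacian minus smoothed) is selectable via `enhance_sign = -1`;
  on typical slide-like images the default accentuates edges (a step
  edge overshoots its smoothed value, which the tests check).
* Border handling everywhere: reflect padding, mirrored about the edge
  pixel (numpy's `reflect` / scipy's `mirror` convention).

## Split and augmentation

Both 80/20 cuts use floor rounding on the 80% side; this is the unique
rounding rule that reproduces all six published per-phase counts from
class sizes 2494/2698, and it is applied per class (stratified).
Membership is a seeded uniform permutation within each class.

The 12-variant augmentation menu is fixed and deterministic: rotations
{90°, 180°, 270°}, flips {horizontal, vertical}, shifts {±10% in x, ±10%
in y, reflect fill, integer pixels}, plus the three 90° rotations of the
horizontally flipped image. One dihedral coincidence is worth knowing:
rot180 ∘ fliph **is** flipv, so the menu's 12 derived images contain 11
distinct pixel arrays. The menu is kept as stated because the ×12 count
is the bookkeeping contract; provenance (source id, transform name) is
attached to every derived image, and augmentation is refused for any
image not in the training phase. In `run_pipeline` the stage is opt-in
(`augment: true`); the synthetic presets are separable enough that the
evaluation suites do not need it.

## Deep features

`conv2d` uses the cross-correlation convention with output size
`floor((H + 2·pad − k)/stride) + 1`; pooling windows and ReLU follow the
usual definitions. All three are checked against brute-force loop
oracles on random instances.

The 4096-wide descriptor contract is served by:

* `stub` — bilinear resize to 32×32, flatten (3072), multiply by a fixed
  seeded Gaussian matrix scaled by 1/√3072. A random projection of raw
  pixels: linear, instant, and sufficient for linearly separable color
  differences.
* `minicnn` — three blocks of (3×3 conv, ReLU, 2×2 max-pool) with
  channels 8/16/32 and seeded fixed (untrained) weights, a coarse
  average-pool, then a seeded linear map to 4096. Exercises the
  primitives end to end at realistic shapes.
* `adapter:<id>` — a registry for pretrained extractors. AlexNet's fc7
  naturally emits 4096 features; ResNet-18's penultimate width is 512,
  not 4096, so any ResNet adapter must name the layer it extracts and
  owns that discrepancy. No adapter ships by default and none is
  required by any test.

Input resize is bilinear to the backbone's `input_size` (227×227
default, the AlexNet convention).

## Handcrafted blocks

* **DWT (12)** — one-level Haar via PyWavelets in periodization mode,
  which for even sizes equals the orthonormal 2×2 block transform
  ((a+b+c+d)/2 and the three half-differences), so Parseval holds
  exactly and an LL coefficient of a constant-c image is 2c. Odd sizes
  are reflect-padded to even first. Per subband (LL, LH, HL, HH): mean,
  population variance, standard deviation.
* **LBP (203)** — the 24 neighbors are all non-center pixels of the 5×5
  window, scanned row-major; bit p is set when `neighbor − center ≥ 0`
  (ties count as 1, the standard convention). The 24-bit code space is
  histogrammed into 203 equal-width bins, the last bin absorbing the
  `2^24 mod 203` remainder, then L1-normalized. The 203-bin reading is a
  design choice: it is the only construction consistent with the
  244 = 12 + 203 + 16 + 13 total, and the feature keeps the defining LBP
  property (invariance to monotone gray shifts), which the tests assert.
* **FCH (16)** — hue from RGB→HSV; 16 centers at j/16 on the hue circle;
  triangular membership splits each pixel's unit mass between the two
  nearest centers with wraparound; achromatic pixels (saturation 0) go
  to bin 0 by convention. L1-normalized, hence permutation-invariant in
  the pixels.
* **GLCM (13)** — gray quantized to 8 equal-width levels over [0, 256);
  offsets (0,1), (−1,1), (−1,0), (−1,−1) for θ = 0°/45°/90°/135°
  (distance 1 axially, √2 diagonally); ordered counts symmetrized and
  normalized. Haralick's 13 statistics use natural logs with 0·log 0 = 0;
  correlation is defined as 0 when a marginal standard deviation is 0
  (constant image). The 13 statistics are averaged over the four
  directions — 13 features total rather than 13 per direction, matching
  the 244-total layout.

Gray conversion (0.299, 0.587, 0.114) happens once per image and is
shared by DWT/LBP/GLCM.

## PCA and fusion

PCA is fitted on training-phase rows only (default) to avoid evaluation
leakage; `pca_fit_on: all` restores the fit-on-everything variant. k
defaults to 1024 and is silently lowered to `min(k, n_train − 1, d)` on
small runs. Component signs are fixed by making each component's
largest-magnitude coordinate positive, so repeated fits are directly
comparable. Fusion is plain column concatenation (deep-PCA block then
handcrafted block) and is exactly invertible by slicing.

## Heads

* **SVM** — `SVC(kernel="linear")` on internally standardized features
  (mean/SD learned from the training rows and stored in the model), C=1
  default. Prediction is the sign of the affine score with ties (score
  exactly 0) going to the positive class, malignant.
* **ANN** — input width d, one hidden tanh layer of 15 units by default
  (`hidden_layout` accepts any tuple; reading the architecture as 10 or
  15 *layers* would be unusable for this problem size, so the counts are
  interpreted as hidden-unit widths), 2-unit softmax output.
  Cross-entropy loss by default, MSE by flag. Plain full-batch gradient
  descent, learning rate 0.01, seeded initialization. Early stopping:
  after 6 consecutive epochs (the `patience`) without a strict
  validation-loss improvement, training stops and the best-validation
  weights are restored, so the restored checkpoint's validation loss is
  never worse than the final epoch's. A non-finite loss raises a
  divergence error carrying the epoch.

## Evaluation

Malignant is the positive class for TP/FP/FN/TN and every metric.
Accuracy, specificity, sensitivity and precision are reported in
percent at full precision (rounding is presentation-only); any metric
with a zero denominator is reported as undefined (`None`), never as 0.
Two AUC-like numbers are emitted: `auc_ratio` = sensitivity/specificity
(a legacy ratio summary) and `roc_auc`, the trapezoidal area under the
TPR-vs-FPR curve, which is the headline AUC since it is the quantity a
ROC curve actually measures. The error histogram uses 20 equal-width
bins over the observed range of (target − output).

## Synthetic data

The generator emulates just the properties the descriptors consume: a
per-class base color (H&E-like pink for normal, darker purple with
lower blue for malignant), soft-edged dark blobs standing in for nuclei
(disks with a Gaussian falloff, evaluated on a 3r support window), a
low-frequency sinusoidal texture, and i.i.d. Gaussian pixel noise. The
"separable" preset (the evaluation condition) uses 100 images per class
at 227×227 with a large color gap and a 3×/9× blob-density contrast;
the "hard" preset narrows the color gap to ~15 intensity units and
doubles the noise. It does **not** model stain physics, optics,
inter-patient variation, pleomorphism or spatial tissue architecture —
so passing tests demonstrate that the pipeline's machinery is correct
and that it recovers class structure when color/texture statistics
carry it, not that any particular accuracy transfers to real slides.

Problem sizes used by the evaluation suites: the dimensionality check
runs 1025 images per class at 64×64 px with the stub backbone (its
training partition, 1312 rows, is what permits the full k = 1024 PCA
and hence the 1268-wide fused vectors); classification checks run the
separable preset at its 227×227 default, 100 images per class, 3 seeds,
with a shuffled-label control expected at chance level.

## Known limitations

* No trained CNN weights are bundled; pretrained backbones are
  adapter-only, and the headline accuracies reported for real OSCC
  collections with ImageNet backbones are out of scope here.
* The ANN optimizer is deliberately plain (fixed-rate full-batch GD);
  it is adequate for the desk-scale separable runs, not tuned for large
  real datasets.
* The 203-bin LBP histogram and the direction-averaged GLCM panel are
  documented interpretations of underspecified descriptor sizes; both
  are locked by the 244-total contract.
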