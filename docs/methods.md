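# Methods

## The problem and the models

A local luminance edge in an achromatic natural image may be a surface
boundary (an *occlusion*) or a cast shadow across one surface. The
package analyzes which locally available achromatic cues separate the two
classes in 40×40-pixel patches centered on the edge, and how two
image-computable observer models use those cues.

### Patch statistics

Patches are assumed to contain a single edge path splitting them into two
regions. Three statistics summarize a patch:

* **RMS contrast** `c_RMS = σ/μ` — population standard deviation of pixel
  intensities over their mean. A descriptive statistic of the patch, so
  the population (not sample) deviation is used.
* **Michelson contrast** `c_M = |μ₂ − μ₁| / (μ₂ + μ₁)` — computed from
  the mean intensities of the two regions. For positive intensities
  `c_M < 1` strictly.
* **High-frequency proportion** `π_h` — the patch is de-meaned and
  energy-normalized, its 2-D power spectrum is binned by rounded integer
  radial frequency `r = round(√(f_x² + f_y²))` in cycles/image, and `π_h`
  is the power at `r > 10` divided by all non-DC power. Nyquist for a
  40×40 patch is 20 cycles/image, so the rotational amplitude curve has
  20 bins. The DC bin is excluded from the denominator (the patch is
  zero-mean, so it is numerically negligible either way; an
  `include_dc` flag restores it). No per-patch [0, 1] renormalization is
  applied by default; feature computations accept any positive-mean
  intensity scale.

### The log-Gabor front-end

V1 simple cells are modeled by a fixed bank of 72 oriented log-Gabor
filters: 3 scales (8-, 16-, 32-pixel square support), 6 orientations
equally spaced in [0, π) starting at vertical (the aligned-edge
orientation), even/odd quadrature phases and ± contrast polarities.
Filters are constructed in the frequency domain — a log-Gaussian radial
profile (hence exactly zero DC) times a Gaussian angular profile with
standard deviation π/12 (half the orientation spacing), restricted to one
orientation half-plane so that the real/imaginary spatial parts form the
even/odd quadrature pair. Center wavelengths equal the filter support
(8, 16, 32 pixels/cycle). The radial width is set analytically so the
half-magnitude bandwidth is 1.5 octaves (verified numerically to
±0.2 octaves in the tests); this value is typical of V1 neurons. Kernels
are unit-L2-normalized and mean-subtracted on the discrete grid.

`apply_frontend` subtracts the patch mean (the filters are zero-DC, but
with zero-padded convolution the mean would otherwise leak in at the
borders; de-meaning also makes "constant patch → zero features" exact),
convolves each filter with 'same'-size zero-padded output, half-wave
rectifies each polarity, and MAX-pools non-overlapping 8×8 blocks down to
5×5, producing 1800 non-negative features laid out as
(scale, orientation, phase, polarity, pool_row, pool_col).

Implementation note: batched convolution is done as a full FFT
convolution cropped at offset (S−1)/2 (floor), which matches
`scipy.signal.fftconvolve(..., mode="same")` for a single kernel; the
adjoint operator (used by the optimal-stimulus gradient) crops the
flipped-kernel full convolution at offset S/2. Both are verified by
inner-product identities and finite differences in the test suite.

### Classifiers

* **GFB**: binomial logistic regression on the 1800 features
  (1801 trainable parameters). The fit is convex; a deterministic
  full-batch quasi-Newton solver (scikit-learn's lbfgs) is used, with L2
  penalty λ on the weights only.
* **FRF**: the same front-end feeding K relu hidden units (K ∈ {4, 6,
  10}) and a logistic readout — the standard filter-rectify-filter
  architecture of second-order (texture) vision; 1800K + 2K + 1
  parameters. Trained by seeded Adam (scikit-learn MLPClassifier) with a
  fixed epoch budget and no early stopping, so the recorded loss curve is
  deterministic for a given seed; the mini-batch loss decreases in moving
  average rather than monotonically.
* **Feature classifier**: logistic regression on (c_M, c_RMS) or
  (+ π_h), features z-scored on the training folds (a flag disables
  standardization).

Model output is an occlusion probability p; the log-odds
`u = ln(p/(1−p))` is the classifier's decision value. u is computed
directly from the linear decision function rather than by inverting p,
because confident models push p to exactly 0 or 1 in double precision,
where the inverse sigmoid is undefined. Probability/log-odds round-trip
to 1e-12 wherever both are representable.

Two evaluation protocols: **by-image blocks** (images partitioned into 5
blocks; train on 4, test on the held-out block; mean over the 5 folds,
reported at the best λ over a grid) estimates generalization to novel
images; **uniform resampling** (train/test sets drawn with replacement
from all patches) estimates generalization to similar patches and is
systematically more optimistic.

### Optimal stimuli

The stimulus maximizing (or minimizing) the model output — or a single
FRF hidden unit — is found by projected gradient ascent on pixel values
clipped to [0, 1], with seeded random restarts. Gradients flow through
the front-end analytically: MAX-pool routes the gradient to each block's
argmax (zero where the rectified maximum is zero), rectification masks by
sign, and the convolution adjoint is as above.

### Stimulus probes

* **Blur/contrast tuning**: vertical step-edge probes (dark left) at
  Michelson contrasts {0.2, 0.4, 0.6} and parametric penumbral blur.
  Blur is an *exact circular Gaussian*: the profile's DFT is multiplied
  by `exp(−2π²σ²f²)`. This choice (rather than a truncated spatial
  kernel with replicated borders) makes the probe's spectral attenuation
  exact, so `π_h` is strictly decreasing in σ — with border-replicating
  blur the FFT's wrap-around discontinuity keeps a constant
  high-frequency floor and the monotonicity genuinely fails. After
  blurring, an affine intensity map pins the two half-patch means, so
  measured contrast equals the nominal level to 1e-6 (in practice to
  machine rounding).
* **Texture removal**: every pixel of each region is set to the region's
  mean; edge-path pixels take the nearer region's mean so both region
  means — hence c_M — are conserved (to float rounding; the operation is
  idempotent at the same precision).
* **Blurred control**: texture removal artificially sharpens the
  boundary, which by itself raises occlusion evidence; the control
  re-blurs with an 8×8 Gaussian kernel (σ = 3 px, truncated and
  normalized to unit sum), applied only to pixels ≥ 8 px from every
  border. The contrast-restoring affine map is solved on the central
  pixels only (a 2×2 linear system pinning both full-region means), so
  border pixels stay bit-identical and c_M is restored exactly.
* **Effect statistics**: per patch, `Δ = u_original − u_manipulated` for
  each model and `D = Δ_FRF − Δ_GFB`. Medians are tested with one-sample
  Wilcoxon signed-rank tests (the data are paired differences; a
  rank-sum variant on the two samples is available through
  `patch_statistics.compare_groups`), grouped by whether each model
  classified the original patch correctly (sign of u).

### Aggregate observer

Per image, `π_i` is the proportion of observers responding "occlusion".
The deterministic reading predicts occlusion iff `π_i ≥ 0.5` (ties count
as occlusion), giving a 2×2 confusion matrix. Error bias is tested with
the exact two-sided binomial test `p = min(1, 2·P(X ≤ min(e₁, e₂)))`,
X ~ Binomial(e₁+e₂, ½) — equivalent to the symmetric two-tailed exact
test. Observer–model agreement is Spearman's ρ with mid-rank ties,
computed on probabilities: ranks are invariant to the logit transform,
so this equals the log-odds correlation while tolerating π ∈ {0, 1}.
Model comparison bootstraps images with replacement (default 1000
replicates, seeded) and reports the median and 2.5/97.5 percentiles of
Δρ. Pooling surveys is concatenation of their image lists. The
observer-screening rule (≥ 114 of 200 correct) is provided as a
parameterized filter; the threshold is a convention of the screening
procedure, not derived from a significance level.

## The synthetic generator

The generator emulates the statistical structure separating the classes
in natural scenes, without reproducing any particular natural image:

* **Textures** are Gaussian noise fields with a `1/f^α` radial amplitude
  envelope (α drawn uniformly from [0.8, 1.6] per patch) and an optional
  oriented energy bias (`exp(κ·cos 2(φ−φ₀))`, κ ∈ [0, 0.8], φ₀ uniform),
  squashed smoothly into (0, 1) by `0.5 + 0.5·tanh(·/2)`. Texture
  similarity s between the two sides of an occlusion is spanned by
  correlating the underlying fields: `f_right = s·f_a + √(1−s²)·f_b`.
* **Shadows** are one texture (tanh-compressed to ≈ ±30% relative depth)
  multiplied by a blurred illumination step whose attenuation
  `(1−c)/(1+c)` already yields the target contrast, so the final exact
  contrast-pinning affine map is nearly the identity. Texture continuity
  across the boundary is preserved; σ ~ Uniform[1, 5] px; contrast ~
  Uniform[0.2, 0.9] (a shadow requires a luminance change).
* **Occlusions** join two textures at a sharp vertical boundary, each
  side shifted to its target mean with a shared texture amplitude capped
  so pixels stay within (0, 1) at high luminance contrast. Contrast is a
  mixture (with probability ½ Uniform[0, 0.25], else Uniform[0, 0.9]),
  concentrating occlusions at low contrast while spanning the full
  range, so both contrast tails belong to occlusions; similarity ~
  Uniform[0, 0.5].
* All patches are pre-aligned (vertical edge, darker side left, edge
  path on the column left of center) and the measured Michelson contrast
  equals the target to machine rounding, enforced by pinning the two
  region means affinely. At extreme contrast/blur combinations a few
  pixels can slightly leave [0, 1]; the PNG writer stores each patch
  min-max scaled with the range recorded in the manifest, making the
  round trip lossless up to 16-bit quantization.
* Patches are grouped into category-pure **pseudo-images** (50 patches
  each by default) so the by-image protocol is exercised; real labeled
  scenes group patches by source photograph in the same way.
* **Pseudo-scenes** render straight edges with soft luminance steps into
  a smooth background, with per-annotator one-pixel edge maps, as
  fixtures for the extraction/vetting/alignment path.
* **Simulated observers** are independent Bernoulli responders with
  specified per-image probabilities.

What the generator does *not* emulate: real surface materials and their
spatial nonstationarity, curved or irregular edge geometry inside the
patch, inter-annotator disagreement about edge position, correlations
between contrast, blur and texture that natural scenes may have, and
non-shadow non-occlusion edge causes (reflectance and material changes,
specularities). Passing tests therefore demonstrate that the
implementation extracts and uses the designed-in cues correctly — not
that the specific accuracy numbers transfer to natural-image databases,
which the loaders support but the tests do not require.

## Patch extraction and alignment

Candidate patches are sampled on labeled edge pixels, cycling through
annotators draw by draw (uniform over each annotator's not-yet-used
pixels, replenished if exhausted). A candidate is accepted iff the
composite edge map inside it is a single 8-connected component whose
removal leaves exactly two 4-connected background regions, the smaller
covering ≥ 35% of all patch pixels — this rejects T-junctions, crossings
and corner-clipping edges. The 8/4 connectivity split is the standard
duality preventing regions from leaking through diagonal edge pixels.
Alignment rotates the patch so the principal axis (PCA of edge-pixel
coordinates) is vertical, using bilinear interpolation; when a larger
source window is available the rotation happens there and the center is
re-cropped, so no out-of-bounds pixels are invented (synthetic fixtures
always provide the window). The partition is re-derived by rotating soft
region/edge indicator images and assigning each pixel to the strongest,
so masks always partition the patch. "Sine phase" is operationalized
purely as the left-darker mirror rule; no phase estimation is performed.
Coordinates are 0-based, row-major, top-left origin.

## Numerical choices and problem sizes

* Contrast pinning, blur-control restoration: exact affine solves; no
  iterative tolerance.
* Logistic fits: lbfgs, tol 1e-8–1e-10; FRF: Adam, fixed 400-epoch
  budget, seeded initialization.
* λ grids: the models support the full log-spaced grid 10⁻³…10³; the
  packaged benchmark uses the coarse sub-grid {0.01, 1, 100}, which is
  where performance plateaus on the synthetic data.
* The packaged benchmark (`pipeline.run_benchmark`, also driven by
  `scripts/acceptance.py` and the acceptance tests) uses 2000 + 2000
  patches in 80 pseudo-images, 5-fold by-image cross-validation, 150
  texture-removal probes, and blur levels 0–4 px at contrasts
  {0.2, 0.4, 0.6}; a full run takes roughly five minutes on one CPU.
* Degenerate inputs raise: constant patches for spectral statistics,
  single-pixel edges for alignment, p ∈ {0, 1} for the log-odds, empty
  regions for Michelson contrast, single-class labels for training.
* Ties: `π = 0.5` counts as occlusion; Spearman uses mid-ranks; the
  MAX-pool argmax takes the first maximum in row-major block order.

## Known limitations

* The exact peak frequencies and angular bandwidth of cortical filters
  are conventions here (wavelength = support size; angular σ = half the
  spacing); only the 1.5-octave radial bandwidth is pinned numerically.
* FRF training is first-order and non-convex; different seeds give
  different hidden units (the convex GFB readout is seed-independent).
* The blur-tuning contrast effect (occlusion evidence falling with
  contrast at zero blur) depends on the generator's contrast mixture and
  is reported, not asserted.
* The synthetic benchmark's absolute accuracies are properties of the
  generator's separability settings, not estimates of performance on any
  natural-image database.
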