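# shadowedge

Tools for studying how **shadow edges** can be told apart from **occlusion
(surface-boundary) edges** using only local achromatic cues in small
grayscale image patches.

A luminance edge in a natural image may mark the boundary between two
surfaces, or merely a cast shadow falling across one surface. Parsing a
scene into surfaces requires telling these apart, and three local
achromatic cues carry the relevant information: **contrast** (both the
highest- and the lowest-contrast edges tend to be occlusions — two
unrelated surfaces can have identical mean luminance, while a shadow
requires a luminance change), **penumbral blur** (shadow borders are
gradual), and **texture** (two surfaces usually differ in texture, one
surface under two illuminations does not).

The package implements, for 40×40 patches:

* **Patch statistics** — RMS contrast `c_RMS = σ/μ`, Michelson contrast
  `c_M = |μ₂ − μ₁| / (μ₂ + μ₁)` over the two regions flanking the edge,
  and `π_h`, the proportion of spectral power above 10 cycles/image
  (Nyquist = 20 for 40×40).
* **A V1-like front-end** — 72 oriented log-Gabor filters (3 scales ×
  6 orientations × even/odd phase × 2 polarities, ≈1.5-octave bandwidth),
  half-wave rectified and MAX-pooled 8×8 → 5×5, giving 1800 features.
* **Two classifiers** — the **GFB** model (logistic readout of the 1800
  features; 1801 parameters) and the **FRF** model (K relu hidden units
  between front-end and readout, the standard second-order texture
  architecture; 1800K + 2K + 1 parameters), plus a plain logistic
  classifier on (c_M, c_RMS, π_h).
* **Stimulus probes** — blur/contrast tuning curves from contrast-exact
  step-edge probes, texture removal (region-mean substitution, Michelson
  contrast conserved exactly), its blurred control, and gradient-based
  optimal-stimulus search through the front-end.
* **Aggregate-observer analysis** — per-image response proportions from a
  pool of observers, confusion matrices under the `π ≥ 0.5` rounding
  rule, exact binomial bias tests on the error split, Spearman
  correlation between observer and model probabilities, and a bootstrap
  comparison of two models' correlations.
* **A synthetic generator** — shadow patches are one texture under a
  multiplicative, penumbrally blurred illumination step; occlusion
  patches are two textures meeting at a sharp boundary, with Michelson
  contrast pinned exactly to its target. It also simulates pseudo-scenes
  with annotated edge maps and Bernoulli observers, so every stage is
  testable without any external data.

## Worked example

```python
import numpy as np
from shadowedge import (
    make_dataset, build_bank, train, predict,
    michelson_contrast, high_freq_proportion,
)
from shadowedge.gabor_frontend import apply_frontend_batch

patches, manifest = make_dataset(n_per_class=200, seed=0)
y = (manifest["category"] == "occlusion").to_numpy().astype(int)

pih = np.array([high_freq_proportion(p.pixels) for p in patches])
print("median pi_h shadow    :", round(np.median(pih[y == 0]), 4))
print("median pi_h occlusion :", round(np.median(pih[y == 1]), 4))

bank = build_bank()
X = apply_frontend_batch(np.stack([p.pixels for p in patches]), bank)
model = train(X, y, kind="gfb", l2_lambda=1.0)
acc = np.mean((predict(model, X).p > 0.5) == y)
print("GFB training accuracy :", round(acc, 3))
```

prints

```
median pi_h shadow    : 0.0107
median pi_h occlusion : 0.0591
GFB training accuracy : 1.0
```

Shadows carry less high-spatial-frequency power than occlusions (the
penumbra removes it), and the filter-bank classifier separates the two
synthetic categories essentially perfectly on its training set; held-out
accuracy on novel pseudo-images is estimated by
`shadowedge.pipeline.run_benchmark`.

A thin CLI mirrors the shell-friendly stages:

```bash
shadowedge synth --n-per-class 200 --out-dir scratch/demo --seed 0
shadowedge stats --patches scratch/demo --out scratch/features.csv
shadowedge benchmark --n-per-class 500 --seed 0
```

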