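# Methods

## Problem

Fruit-sorting lines inspect curved, glossy produce with hyperspectral
cameras. Pixel spectra carry the biochemical signature of the tissue, but
the measured signal also depends on illumination geometry: shading over a
curved surface modulates brightness, and specular glints reflect the lamp
spectrum without penetrating the tissue at all. This package implements
and compares a complete pixel-level defect-segmentation pipeline under
three acquisition protocols:

* **local** — one lamp at 45° zenith; reflectance by flat-field division
  `R = I_obj / I_ref` against a white reference plate;
* **simultaneous** — three lamps at the same zenith, different azimuths,
  emulated by summing the per-lamp signals before division,
  `R = Σ_i I_obj,i / Σ_i I_ref,i`;
* **sequential** — one exposure per lamp, followed by a per-pixel
  constrained decomposition of the angular reflectance series into a
  diffuse (volume) component and a specular component.

Four pixel classifiers run on each recovered reflectance cube: a spectral
angle mapper (SAM), a 100-tree random forest, an RBF-kernel SVM and a
shallow 1-D convolutional network. Performance is scored by accuracy,
error rate (percent), precision, recall, specificity, F1 and IoU with
defect as the positive class.

## Specular/diffuse decomposition

Per pixel, the per-lamp reflectance is modeled as

    R_i(λ) = R_vol(λ) + ε_i · R_surf(λ),      i = 1..3,

with box bounds `R_vol ∈ [0,1]`, `R_surf ∈ [0,0.1]`, `ε_i ∈ [0,1]`. The
fit minimizes the squared misfit summed over lamps and bands.
Initialization follows the protocol the model was designed with: `R_vol`
starts at the angle-averaged spectrum, `R_surf` at a constant 0.05, and
each `ε_i` at the least-squares regression of that lamp's residual onto
the initial `R_surf`, clipped into bounds.

**Solver.** The model is bilinear, so the bounded problem is solved by
block coordinate descent rather than a generic trust-region least-squares
routine: holding the other blocks fixed, each of `R_vol` (per band),
`R_surf` (per band) and `ε` (per lamp) is a separable one-dimensional
quadratic whose box-projected minimizer is exact. Every sweep therefore
decreases the objective monotonically, the iteration vectorizes over all
pixels of a frame simultaneously, and 10⁴–10⁵ pixels converge to
machine-level residuals in seconds to a couple of minutes on one CPU.
Defaults: at most 500 sweeps, relative objective-decrease tolerance
10⁻¹², non-converged pixels keep their best iterate and are flagged in a
convergence map (the solve never raises mid-frame).

**Gauge.** The decomposition is not unique:
`(R_vol + β·R_surf, α·R_surf, (ε−β)/α)` fits identically. The products
`ε_i·R_surf` are gauge-invariant; to make `R_vol` itself well defined the
result is canonicalized to the representative with `min_i ε_i = 0` at
every pixel — physically, at least one lamp position sees no glint. The
shift preserves the residual exactly and, at exactly-fitted pixels,
makes `R_vol` equal the minimum per-lamp reflectance. It is applied by
default and can be disabled (`fix_gauge=False`).

**Model mismatch.** The model contains no shading term. Under per-lamp
Lambertian shading the angular variation of the diffuse signal is partly
absorbed by `ε_i·R_surf` and partly left as residual; `R_vol` then tracks
the darkest-lamp envelope rather than the unshaded tissue reflectance.
Spectral *shape* — all that scale-invariant classification uses — is
preserved well; absolute amplitude is not. Exact-recovery guarantees are
therefore stated for shading-free scenes only.

## Calibration and object extraction

Each spectral image (object and reference, every band) is denoised with a
3×3 spatial median filter before any reflectance recovery. Division by a
non-positive reference marks a pixel invalid rather than propagating
infinities; invalid pixels are excluded from masks and datasets.

Objects are located by thresholding the 750 nm band — high contrast
between fruit and dark background — with Otsu's method, filling holes
(dark defect patches inside a silhouette), labeling 8-connected
components and keeping those whose area falls in a window of
20,000–40,000 px at the native magnification (a fruit of radius ≈90 px).
For scenes generated at smaller scale the window is scaled by the square
of the radius ratio. The Otsu threshold maximizes between-class variance
over a 256-bin histogram of the data range; bin moments are integers, so
the maximization is carried out in exact integer arithmetic and
plateaus (runs of empty bins) tie-break deterministically to the first
maximizing split.

Within one experiment the object mask is computed once, on the
multi-lamp averaged reflectance, and shared by all three modes: averaging
azimuths yields the most complete silhouette (a single 45° lamp shades
the far limb of a sphere below the Otsu cut), and the same physical
objects underlie every mode of a scene. Per-mode masking remains
available through `build_object_masks`. Before pixels enter the
datasets or prediction masks the silhouette is eroded by one pixel per
pixel of median-filter support (default 1): rim spectra are mixtures of
fruit and dark background after the 3×3 filter, and amplitude-sensitive
classifiers would otherwise mark the rim as defect.

## Dataset protocol

Every labeled fruit pixel is one sample. The train/test split is made at
the level of whole fruits, 40/60 by default; among 50 seeded candidate
partitions the one minimizing the difference in defect-pixel proportion
between the two sides is kept, and the same partition is shared by all
classifiers and all illumination modes of an experiment. The healthy
class is randomly under-sampled (without replacement, seeded) in the
training set to match the defect count; defect pixels are never dropped.
Evaluation pools confusion counts over all test fruits inside the object
masks (background excluded); per-object metrics and per-object averaging
are available by flag.

## Classifiers

* **SAM** — per-class mean training spectra, unit-normalized; each pixel
  scores the cosine of the angle to the healthy reference. Below the
  threshold ⇒ defect. Two thresholding variants exist: a fixed value
  (0.2 by default at the operation level) and an Otsu cut on the
  similarity distribution of the pixels being classified. The experiment
  driver defaults to the Otsu variant: on phantom spectra every cosine
  similarity exceeds 0.9, so a fixed 0.2 on the cosine scale separates
  nothing — the fixed value is only meaningful on the spectral-angle
  (arccos) scale, which is available via `use_angle=True`. The adaptive
  variant computes the Otsu cut over a histogram range trimmed of the
  lowest 1% of similarities: a handful of extreme outliers (deep glare
  rims on shaded defect tissue) otherwise stretch the 256-bin range
  until every class crowds into a few bins; trimmed pixels are the most
  dissimilar ones and land on the defect side of the cut regardless. Glare pixels
  (broadband mean above the 99.5th percentile of masked pixels *and*
  above 0.9 absolute, dilated by one pixel; both knobs configurable) are
  excluded from the similarity maps and forced to healthy: glints carry
  no tissue information, and defective skin loses the turgor needed to
  produce them.
* **Random forest** — 100 trees, Gini splits, unlimited depth, √B
  features per split, bootstrap aggregation with the out-of-bag error
  recorded.
* **SVM** — RBF kernel, C=1, SMO-style solver capped at 10,000
  iterations. The kernel scale is the median pairwise distance over a
  seeded subsample of ≤1,000 training spectra (`γ = 1/(2s²)`). Training
  is capped at 20,000 stratified pixels; the cap, scale and convergence
  status are recorded in the model metadata.
* **1-D CNN** — three convolutional blocks along the spectral axis
  (kernel length 5, 8 feature maps, same padding, batch normalization,
  ReLU), global average pooling, dense layers of 64 and 16 with ReLU and
  a 2-way softmax (2,402 parameters at 81 bands). Trained with Adam at
  initial rate 10⁻³ on mini-batches of 4,096 spectra, cross-entropy
  loss, no early stopping. The implementation is pure numpy with full
  backpropagation, so training is bit-deterministic for a given seed.
  The default is 30 epochs; the experiment driver holds the optimizer
  budget near 500 Adam updates by raising the epoch count when the
  balanced training set is small, so that reduced-scale scenes receive
  the same effective optimization as a full-scale session.

## Synthetic phantom

No public dataset accompanies the protocol, so all testing runs on a
generated phantom with pixel-exact ground truth. One frame holds a grid
of non-overlapping disk "fruits" (default radius configurable; a fruit
of radius 90 px occupies ≈25,400 px, inside the native area window).
Half of the fruits carry one circular defect patch each, fully inside
the fruit.

* **Tissue spectra.** Healthy tissue is a smooth logistic red-edge curve
  with a green bump (≈0.05 in the blue to ≈0.40 in the NIR); defect
  tissue is darkened and spectrally flattened
  (`0.12 + 0.35·(h − mean(h))`), emulating bruise/rot. A smooth ±8%
  multiplicative field adds within-class amplitude variation. The
  darkening/flattening level is chosen so that strongly glare-
  contaminated healthy spectra are at least as dissimilar from the
  healthy reference as defect spectra — the regime in which glare areas,
  if not excluded, are misread as defects by angle-based classification,
  which is the qualitative behavior the pipeline is designed to study.
* **Specular truth.** `R_surf` rises 0.07→0.09 across the band — near
  the model's 0.1 ceiling, since real glints on glossy skin are
  dominated by the surface component. Each lamp projects one saturated
  flat-top glare lobe per fruit (amplitude 1.0 over a core of 0.18·r,
  Gaussian rim of 0.10·r, truncated below 0.05), offset toward the lamp
  azimuth. Lobes of different lamps do not all overlap, so at every
  fruit pixel at least one lamp is glare-free — the condition that makes
  `R_vol` identifiable.
* **Shading.** Lambertian cosine factor from a hemispherical height
  profile with lamps at 45° zenith and azimuths 0°/120°/240°, floored at
  0.25 (ambient fill); `shading="none"` disables it.
* **Rendering.** The reference cube is a halogen-shaped lamp spectrum
  (3000 K Planck curve) over a unit-reflectance white plate filling the
  frame; the object cube is
  `I_ref · (s_i·R_vol + ε_i·R_surf)` plus multiplicative Gaussian noise
  (default sd 1% of signal) clipped at zero. Background reflectance is
  0.02.

**What the phantom does not emulate:** additive stray light and read
noise (shadow spectra stay exactly proportional to lit spectra, so
scale-invariant classifiers are immune to shading here in a way they are
not on real data), saturation and blooming, chromatic lamp differences,
wavelength miscalibration, spatial point-spread, and rot progression
over days. Passing tests on phantoms therefore demonstrate correctness
of the pipeline and the qualitative illumination-mode effects, not
absolute performance on real produce.

## Numerical and design choices

* Eq-level identities used in testing: `F1 = 2TP/(2TP+FP+FN)`,
  `IoU = F1/(2−F1)`, `accuracy + error_rate/100 = 1`. Undefined ratios
  (zero denominators) propagate as NaN, never as 0.
* Error rate is always reported in percent.
* Connected components use 8-connectivity (4-connectivity would split
  thin silhouette rims).
* All randomness (scene, noise, split, under-sampling, bagging, SVM
  subsampling, CNN initialization and shuffling) derives from explicit
  integer seeds; an experiment spawns child seeds from one master seed,
  and regenerating a bundle from the same configuration reproduces every
  CSV number exactly.
* Default experiment scale: one 300×600 frame with 18 fruits of radius
  24 px for the full method×mode grid, and ≥10⁴ fruit pixels for the
  decomposition recovery check — sizes chosen so the complete analysis
  runs in minutes on a single CPU while keeping several thousand defect
  pixels in the test partition.

## Known limitations

* The decomposition's amplitude scale under shading is the darkest-lamp
  envelope (see gauge note); downstream consumers needing absolute
  reflectance should disable shading or model it explicitly.
* The SVM's duplicate-invariance and two-point geometry hold only for
  separable data with unbound support-vector coefficients.
* The glare-exclusion rule is intentionally conservative on phantoms
  (phantom glints never exceed 0.9 absolute reflectance, so the rule
  only activates on data with saturated highlights).
* With very few fruits the balanced training set can be small; the CNN
  epoch scaling compensates for the optimizer budget but not for the
  reduced spectral diversity.
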