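# hsiseg

Hyperspectral fruit-defect segmentation under three illumination
protocols, with specular/diffuse reflectance decomposition and a
synthetic multi-angle phantom generator.

Automated produce inspection classifies every pixel of a hyperspectral
cube `I(x, y, λ)` (450–850 nm, 5 nm steps, 81 bands) as background,
healthy tissue or defect. The measured signal confounds tissue chemistry
with illumination geometry: curved fruit surfaces shade, and glossy skin
throws specular glints that carry the lamp spectrum instead of the
tissue's. This package implements a complete, reproducible pipeline for
comparing how four standard pixel classifiers behave under three
acquisition protocols:

* **local** — single 45° lamp, flat-field reflectance
  `R = I_obj / I_ref`;
* **simultaneous** — three lamps, signals summed before division,
  `R = Σᵢ I_obj,i / Σᵢ I_ref,i`;
* **sequential** — one exposure per lamp, then a per-pixel constrained
  least-squares decomposition
  `Rᵢ(λ) = R_vol(λ) + εᵢ·R_surf(λ)` with `R_vol ∈ [0,1]`,
  `R_surf ∈ [0,0.1]`, `εᵢ ∈ [0,1]`, isolating the diffuse (volume)
  component `R_vol` that carries the biochemical signal.

The classifiers — spectral angle mapper (SAM), 100-tree random forest,
RBF-kernel SVM and a shallow 1-D CNN — are scikit-learn-style estimators
(`fit`/`predict`/`get_params`) over pixel spectra, scored by accuracy,
error rate (%), precision, recall, specificity, F1 and IoU with defect
as the positive class. Because no raw dataset is distributed with the
protocol, a first-class phantom generator renders multi-angle scenes
(tomato-like tissue spectra, darkened/flattened defect patches,
saturated per-lamp glare lobes, Lambertian shading, halogen-shaped
references, detector noise) with pixel-exact ground truth.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from hsiseg import (ExperimentConfig, PhantomConfig, run_experiment)

config = ExperimentConfig(
    phantom=PhantomConfig(height=240, width=480, n_fruits=12,
                          fruit_radius=24, noise_sd=0.01, seed=5),
    modes=("local", "sequential"), methods=("sam",), master_seed=1)
result = run_experiment(config)
print(result.grid().loc[["f1", "precision", "recall"]])
```

prints

```
           sam_local  sam_sequential            best
f1            0.4657          0.9243  sam_sequential
precision     1.0000          1.0000       sam_local
recall        0.3035          0.8593  sam_sequential
```

The spectral angle mapper collapses under single-lamp illumination:
saturated glare lobes contaminate healthy-pixel spectra with the flat
specular component until they look at least as unlike the healthy
reference as true defects, and the adaptive similarity threshold
retreats past most of the defect cluster (recall 0.30). Once the
sequential-mode decomposition strips the specular term and classifies
the diffuse component alone, recall recovers to 0.86 and F1 doubles.
(Exact numbers vary with the scene seed; the ordering is stable.)

Lower-level building blocks are available individually:
`make_phantom_scene`/`render_illumination_set` (scenes),
`median_filter_bands`, `reflectance_local`, `reflectance_simultaneous`,
`SpecularDecomposition` (calibration), `build_object_masks`,
`extract_object_cubes` (object isolation), `split_fruitwise`,
`undersample_healthy` (protocol), `SAMClassifier`,
`SpectralForestClassifier`, `SpectralSVMClassifier`,
`SpectralCNNClassifier`, `predict_map` (segmentation) and
`metrics_from_confusion`/`report_metric_grid` (evaluation).

A CLI mirrors the pipeline stages:

```sh
hsiseg generate --fruits 4 --radius 40 --seed 1 --out scene/
hsiseg preprocess --bundle scene/ --mode sequential --out prep/
hsiseg train --bundle scene/ --reflectance prep/reflectance_sequential \
             --method rf --out model/
hsiseg predict --model model/ --reflectance prep/reflectance_sequential \
               --mask prep/object_mask.png --out decision.png
hsiseg evaluate --pred decision.png --truth scene/labels.png
hsiseg run --config experiment.yaml --out results/
```

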