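# roicrop

Segmentation-driven cropping of medical image slices into fixed-geometry
deep-learning patches — built for prostate MRI, applicable to any 2D
slice stack with binary ROI masks.

Clinical T2-weighted prostate images vary in size (256–1024 px), pixel
spacing (≈0.2–0.8 mm) and gland position, while classification networks
want fixed-size, fixed-resolution inputs with a sensible balance of
foreground and background. Naive center-of-image cropping fails whenever
the gland is off-center. `roicrop` instead crops around the *segmented*
ROI: it resamples each slice to a target spacing, samples patches with
one of three strategies, filters them by a minimum in-crop ROI area, and
assembles split, balanced datasets with full per-patch provenance.

## The sampling model

For a slice with `N_roi` ROI pixels and a patch of `N_crop = H_im x W_im`
pixels:

* **center** — one patch centered on the ROI centroid;
* **random** — patches centered at uniformly drawn ROI pixels, with budget

  `N_samples = floor(N_roi / N_crop * C_random)`

  (e.g. `N_roi = 10,000`, 128×128 crop: the ratio is 0.610, so factor
  `C_random = 10` yields 6.10 → 6 samples);
* **stride** — a window lattice stepping `C_stride` px over the ROI's
  bounding box (rounded up to stride multiples), counted per axis by
  `max(1, (L_box − L_im)/C_stride + 1)`.

A patch is kept only if it strictly satisfies
`C_min_area < n_roi_in_crop × pixel_spacing²`
(defaults: 1 cm² of gland for negative cases, 0.2 cm² of lesion for
positive cases). Case health status routes which mask is sampled:
positive cases sample lesions (training never emits lesion-free patches
from positive patients); negative/unknown cases sample the gland.
Validation and test splits are always stride-sampled over the gland so
the whole ROI is covered at evaluation. See `docs/methods.md` for the
full model, parameter table and design rationale.

## Worked example

The package ships a phantom generator (elliptical glands, disk lesions,
realistic size/spacing jitter), so the whole pipeline runs without any
patient data:

```bash
roicrop phantom --n-pos 2 --n-neg 2 --seed 5 --out cohort
roicrop crop --cases cohort/cases.csv --out run1 \
    --size 128 --spacing 0.4 --strategy stride --seed 3
```

which prints

```
split    label  n_images
train negative        16
train positive        16
32 patches -> run1
```

— 4 phantom cases cropped at 128×128 px / 0.4 mm spacing: 16 patches
sampled over the glands of the 2 negative cases and 16 over the lesions
of the 2 positive cases, each patch strictly exceeding its per-status
minimum ROI area. `run1/` holds the NIfTI patches, `manifest.csv` (one
row per patch: case, slice, origin, label, in-crop ROI area mm², file),
`summary.csv` and a JSON config sidecar. The same library surface is
importable directly (`roicrop.build_dataset`, `roicrop.random_crop`, …),
and `roicrop sweep` runs the full size × spacing × strategy grid
(30 settings by default; 64 px with 0.2/0.3 mm spacing is excluded as
physically too small unless `--allow-small`).

```python
import roicrop as rc

rc.n_random_samples(10_000, 128 * 128, 10)   # -> 6
```

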