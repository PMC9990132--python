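# Methods

## Problem and model

Deep learning models for prostate MRI classification take fixed-size 2D
inputs, while clinical T2-weighted acquisitions vary in image size
(256–1024 px square), in-plane pixel spacing (roughly 0.2–0.8 mm) and
gland position. `roicrop` standardizes the conversion of segmented slice
stacks into fixed-geometry training patches. The pipeline per case is:

1. **Resample** each slice (intensity + masks) to a chosen target pixel
   spacing.
2. **Select** slices: only gland-bearing slices, excluding the first
   (apex) and last (base) gland slice.
3. **Route** by health status: positive cases sample the *lesion* mask
   (patches labeled positive), negative and unknown cases sample the
   *gland* mask (labeled negative / unlabeled). A lesion mask is used
   only when at least half of its pixels lie inside the gland mask.
4. **Sample** patches with one of three strategies (below).
5. **Filter** each candidate patch by a strict minimum in-crop ROI area.
6. **Write** patches and a per-patch provenance manifest.

### Sampling strategies

With `N_roi` the number of ROI pixels in the slice and `N_crop = H_im x
W_im` the patch pixel count:

* **center** — one patch centered on the ROI centroid (mean of positive
  pixel coordinates, rounded half away from zero per axis).
* **random** — patches centered at pixels drawn uniformly *with
  replacement* from the ROI; the accepted-patch budget is

  `N_samples = floor(N_roi / N_crop * C_random)`

  so the budget scales automatically with pixel spacing, ROI size and
  crop size. Candidates failing the area filter are redrawn up to
  `max_redraw_factor x budget` draws (default factor 10); a shortfall is
  logged, never an error.
* **stride** — a deterministic window lattice over the ROI's tight
  bounding box, expanded (anchored at its top-left corner) so its height
  and width are multiples of `C_stride`; per axis the window count is

  `max(1, (L_box - L_im) / C_stride + 1)`

  enumerated row-major, top-left to bottom-right. The division uses
  floor when the slack is not a multiple of the stride (this can only
  happen when the window size itself is not a stride multiple); the
  clamp to 1 guarantees one covering window for ROIs smaller than the
  window.

Every candidate window is clamped to lie fully inside the image when the
image is at least window-sized; only when the image itself is smaller is
the patch zero-padded symmetrically and flagged. Clamping rather than
padding avoids fabricating background in normal-sized images.

### Minimum-area filter

A patch is kept iff `C_min_area < n_in_crop_roi_px x spacing_row x
spacing_col` — a **strict** inequality, applied per candidate crop on the
resampled grid. A cheap slice-level pregate skips slices whose whole-ROI
area already fails the threshold, since no crop could then pass. Default
thresholds: 100 mm² (1 cm²) of gland for negative/unknown cases, 20 mm²
(0.2 cm²) of lesion for positive cases.

### Dataset assembly

Cases are split per class into train/val/test (default 70/15/15): val
and test each take the nearest integer to their fraction of the class
size with exact halves rounded down, the remainder goes to train. This
convention uniquely reproduces the published per-class counts for a
1050-negative / 425-positive cohort (736/157/157 and 297/64/64). Classes
with fewer than 3 cases go entirely to train (warning).

Validation and test splits are always stride-sampled over the **gland**
ROI of both statuses (same `C_stride`, per-status `C_min_area`), so the
whole gland is covered at evaluation; negative-appearing patches from
positive cases can therefore occur in val/test, which full coverage
requires. Training positives sample lesions via the routing above.

`balance_images` undersamples negative manifest rows without replacement
to the positive row count (image level, not case level); if negatives
are the minority, all are kept with a warning.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| crop size | 128 px (grid 64/128/256) | output patch side |
| target spacing | 0.5 mm (grid 0.2/0.3/0.4/0.5) | resampled pixel size |
| `C_random` | 12 | random-crop oversampling factor |
| `C_stride` | 32 px | stride between windows |
| `C_min_area` | 100 mm² gland / 20 mm² lesion | strict patch filter |
| lesion overlap min | 0.5 | lesion-in-gland retention fraction |
| split fractions | 0.70/0.15/0.15 | per-class assignment |
| `max_redraw_factor` | 10 | random-crop rejection budget |

The combinations 64 px with 0.2 or 0.3 mm spacing give physically tiny
patches (≤ 19.2 mm square) and are refused by the CLI unless
`--allow-small` is passed; the sweep grid marks them excluded, leaving
30 settings in the default 3-strategy × 3-size × 4-spacing grid.

## Numerical choices

* **Resampling** is delegated to SimpleITK: cubic B-spline (order 3) for
  intensities, nearest neighbor for masks, both with zero
  boundary-extension outside the source domain. Intensity values are not
  clipped after interpolation; B-spline overshoot near edges is retained
  (writers may rescale at serialization). Identity-spacing plans return
  a copy, so the no-op invariant holds bitwise.
* **Target grid size** = physical extent / target spacing, rounded half
  away from zero with a floor of 1 px, keeping extent error ≤ half a
  target pixel per axis.
* **Coordinates** are 0-based, (row, col), with half-open boxes; all
  rounding tie-breaks are half-away-from-zero.
* **Through-plane spacing** is carried as metadata but never resampled;
  slices are processed independently (3D cropping is out of scope).
* **Determinism**: all randomness flows from `numpy.random.default_rng`;
  per-slice seeds are derived with `SeedSequence(base_seed, case_index,
  slice_index)`, so identical config + seed gives byte-identical
  manifests and patch files across runs. Manifest `path` entries are
  relative to the output directory to keep runs comparable.

## The phantom generator

Phantoms exist so every pipeline stage is testable with no patient data.
A case is: an elliptical gland whose per-slice semi-axes follow a taper
profile (scale `0.3 + 0.7*sqrt(1 - t^2)` across the gland span, small at
apex/base, ≥ 3 gland slices by construction); optional disk lesions
placed inside the gland (intersected with it, so inside lesions have
overlap fraction exactly 1) or straddling its border; intensity = smooth
planar background gradient + gland/lesion contrast + additive Gaussian
noise (a magnitude approximation of Rician MR noise — adequate because
the pipeline's behavior depends on geometry, not noise statistics).

Cohorts jitter image size over {256…1024} px and pixel spacing within
[0.2, 0.8] mm, jointly constrained so the field of view stays in
100–240 mm (a realistic pelvic FOV; unconstrained draws would produce
fields of view too small to contain a gland). Gland semi-axes are drawn
from 14–24 mm × 17–28 mm, center offsets up to ±15% of the image
half-extent, lesion radii 4–8 mm.

What phantoms do **not** emulate: MR physics (bias fields, Rician noise,
partial-volume effects), anatomy beyond ellipse/disk primitives,
multi-focal or irregular lesions, segmentation error. Passing tests
therefore demonstrate correct geometry, routing, filtering, counting and
reproducibility — not clinical performance on real MRI.

## Problem sizes used in checks

The test-suite and the acceptance script run at desk scale by design:
cohorts of 4–20 phantom cases, image sides 256–1024 px, 10–12 slices per
case, single settings (128 px at 0.4–0.5 mm) rather than the full
30-setting sweep; the stride-count formula is validated against a
brute-force placement enumeration on 1,000 random box/window/stride
tuples. The grid cardinality (30) is checked by enumeration.

## Known limitations

* Slice-wise 2D only; no through-plane resampling or 3D windows.
* Random sampling is with replacement: duplicate or heavily overlapping
  patches are possible (deduplication would distort the sample budget).
* Small lesions with large patches and coarse spacing can floor the
  random budget to zero — a property of the budget formula, not a bug;
  use stride sampling or finer spacing in that regime.
* No intensity normalization: the tool crops; normalization (e.g. a
  reference-tissue method) belongs upstream and can be hooked in before
  cropping.
* DICOM series input is an extension point, not implemented; inputs are
  NIfTI or MetaImage.
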