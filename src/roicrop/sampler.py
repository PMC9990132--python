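"""The three crop-sampling strategies: center, random, and stride.

All samplers operate on a slice that has already been resampled to the
target spacing, together with the routed ROI mask (gland or lesion,
depending on case status).  Every emitted patch satisfies the
minimum-ROI-area filter strictly: ``in_crop_roi_area_mm2 > c_min_area_mm2``.

Window placement: a candidate window is clamped so it lies fully inside
the image whenever the image is at least as large as the window; only
when the image itself is smaller than the window is the patch zero-padded
(symmetrically) and flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from .core import (Box, CropResult, CropSpec, Grid2D, ROIStats, SliceSample,
                   roi_stats, round_half_away)

logger = logging.getLogger(__name__)


def n_random_samples(n_roi_px: int, n_crop_px: int, c_random: float) -> int:
    """Random-crop sample budget: ``floor(n_roi_px / n_crop_px * c_random)``.

    The budget scales with the ratio of ROI pixels to patch pixels, so the
    choice of ``c_random`` is unaffected by pixel spacing, ROI size and
    crop size.
    """
    if n_crop_px < 1:
        raise ValueError("n_crop_px must be >= 1")
    if c_random <= 0:
        raise ValueError("c_random must be positive")
    if n_roi_px < 0:
        raise ValueError("n_roi_px must be nonnegative")
    return int(math.floor(n_roi_px / n_crop_px * c_random))


class ExtractedWindow(NamedTuple):
    patch: np.ndarray
    origin_rc: Tuple[int, int]
    padded: bool


def extract_window(raster: np.ndarray, origin_rc: Tuple[int, int],
                   out_h_px: int, out_w_px: int) -> ExtractedWindow:
    """Copy an exact-size window out of ``raster``.

    The requested origin is clamped so the window lies inside the raster.
    If the raster is smaller than the window along an axis, the full
    raster extent is taken on that axis and zero-padded symmetrically;
    the result is flagged ``padded``.
    """
    h, w = raster.shape
    r0 = int(np.clip(origin_rc[0], 0, max(0, h - out_h_px)))
    c0 = int(np.clip(origin_rc[1], 0, max(0, w - out_w_px)))
    take_h = min(out_h_px, h)
    take_w = min(out_w_px, w)
    window = raster[r0:r0 + take_h, c0:c0 + take_w]
    if take_h == out_h_px and take_w == out_w_px:
        return ExtractedWindow(window.copy(), (r0, c0), False)
    pad_top = (out_h_px - take_h) // 2
    pad_left = (out_w_px - take_w) // 2
    patch = np.zeros((out_h_px, out_w_px), dtype=raster.dtype)
    patch[pad_top:pad_top + take_h, pad_left:pad_left + take_w] = window
    return ExtractedWindow(patch, (r0, c0), True)


def _in_crop_area_mm2(mask: np.ndarray, origin_rc: Tuple[int, int],
                      spec: CropSpec, grid: Grid2D) -> float:
    win = extract_window(mask, origin_rc, spec.out_h_px, spec.out_w_px)
    return float(win.patch.sum()) * grid.pixel_area_mm2


def _patch_grid(spec: CropSpec) -> Grid2D:
    return Grid2D(spec.out_h_px, spec.out_w_px,
                  spec.target_spacing_mm[0], spec.target_spacing_mm[1])


def _make_result(sample: SliceSample, roi_mask: np.ndarray,
                 origin_rc: Tuple[int, int], spec: CropSpec, strategy: str,
                 label: str, case_id: str) -> Optional[CropResult]:
    """Extract the window at ``origin_rc`` and apply the min-area filter."""
    win = extract_window(sample.intensity, origin_rc,
                         spec.out_h_px, spec.out_w_px)
    mask_win = extract_window(roi_mask, origin_rc,
                              spec.out_h_px, spec.out_w_px)
    area = float(mask_win.patch.sum()) * sample.grid.pixel_area_mm2
    if not area > spec.c_min_area_mm2:
        return None
    return CropResult(
        patch=win.patch,
        origin_rc=win.origin_rc,
        grid=_patch_grid(spec),
        in_crop_roi_area_mm2=area,
        label=label,
        case_id=case_id,
        slice_index=sample.slice_index,
        strategy=strategy,
        padded=win.padded,
    )


def _center_to_origin(center_rc: Tuple[int, int],
                      spec: CropSpec) -> Tuple[int, int]:
    return (center_rc[0] - spec.out_h_px // 2,
            center_rc[1] - spec.out_w_px // 2)


def center_crop(sample: SliceSample, roi_mask: np.ndarray, spec: CropSpec,
                roi: Optional[ROIStats] = None, *,
                label: str = "unlabeled", case_id: str = "") -> List[CropResult]:
    """At most one patch centered on the ROI centroid.

    The centroid is rounded half away from zero per axis; the window is
    clamped into the image.  Returns an empty list for an empty ROI or
    when the patch fails the minimum-area filter.
    """
    if roi is None:
        roi = roi_stats(roi_mask, sample.grid)
    if roi.n_roi_px == 0:
        return []
    center = (round_half_away(roi.centroid_rc[0]),
              round_half_away(roi.centroid_rc[1]))
    res = _make_result(sample, roi_mask, _center_to_origin(center, spec),
                       spec, "center", label, case_id)
    return [] if res is None else [res]


def random_crop(sample: SliceSample, roi_mask: np.ndarray, spec: CropSpec,
                seed: int, roi: Optional[ROIStats] = None, *,
                label: str = "unlabeled", case_id: str = "") -> List[CropResult]:
    """Patches centered at uniformly drawn ROI pixels (with replacement).

    The number of accepted patches is the budget from
    :func:`n_random_samples`; candidates failing the minimum-area filter
    are redrawn, up to ``max_redraw_factor x budget`` total draws.  A
    fixed seed gives a bit-identical patch list.
    """
    if roi is None:
        roi = roi_stats(roi_mask, sample.grid)
    if roi.n_roi_px == 0:
        return []
    budget = n_random_samples(roi.n_roi_px, spec.n_crop_px, spec.c_random)
    if budget == 0:
        return []
    coords = np.argwhere(roi_mask > 0)
    rng = np.random.default_rng(seed)
    results: List[CropResult] = []
    max_draws = spec.max_redraw_factor * budget
    draws = 0
    while len(results) < budget and draws < max_draws:
        draws += 1
        r, c = coords[int(rng.integers(len(coords)))]
        res = _make_result(sample, roi_mask,
                           _center_to_origin((int(r), int(c)), spec),
                           spec, "random", label, case_id)
        if res is not None:
            results.append(res)
    if len(results) < budget:
        logger.warning(
            "random_crop: %d/%d samples accepted after %d draws "
            "(case=%s slice=%d)", len(results), budget, draws,
            case_id, sample.slice_index)
    return results


@dataclass(frozen=True)
class StrideGrid:
    """The deterministic window lattice of stride cropping.

    ``box`` is the ROI tight box expanded (anchored at its top-left) so
    height and width are the smallest multiples of ``c_stride`` at least
    as large as the tight extents.  Origins are enumerated row-major,
    top-left to bottom-right.
    """

    box: Box
    n_rows: int
    n_cols: int
    origins: Tuple[Tuple[int, int], ...]


def _round_up_multiple(x: int, m: int) -> int:
    return int(math.ceil(x / m) * m)


def stride_grid(roi: ROIStats, spec: CropSpec,
                grid: Optional[Grid2D] = None) -> StrideGrid:
    """Enumerate stride-crop window origins over the ROI's covering box.

    Per axis the window count is ``max(1, (Lbox - Lwin) // c_stride + 1)``
    where ``Lbox`` is the tight extent rounded up to a multiple of
    ``c_stride``; a box smaller than the window still yields one covering
    window.  Empty ROI yields an empty grid.
    """
    if roi.n_roi_px == 0 or roi.tight_box is None:
        return StrideGrid(Box(0, 0, 0, 0), 0, 0, ())
    s = spec.c_stride
    tb = roi.tight_box
    h_box = _round_up_multiple(tb.height, s)
    w_box = _round_up_multiple(tb.width, s)
    n_rows = max(1, (h_box - spec.out_h_px) // s + 1)
    n_cols = max(1, (w_box - spec.out_w_px) // s + 1)
    origins = tuple((tb.top + i * s, tb.left + j * s)
                    for i in range(n_rows) for j in range(n_cols))
    return StrideGrid(Box(tb.top, tb.left, h_box, w_box),
                      n_rows, n_cols, origins)


def stride_crop(sample: SliceSample, roi_mask: np.ndarray, spec: CropSpec,
                roi: Optional[ROIStats] = None, *,
                label: str = "unlabeled", case_id: str = "") -> List[CropResult]:
    """A window at every stride-grid origin (clamped in-image), filtered.

    Fully deterministic; no randomness is involved.
    """
    if roi is None:
        roi = roi_stats(roi_mask, sample.grid)
    if roi.n_roi_px == 0:
        return []
    sg = stride_grid(roi, spec, sample.grid)
    results: List[CropResult] = []
    for origin in sg.origins:
        res = _make_result(sample, roi_mask, origin, spec, "stride",
                           label, case_id)
        if res is not None:
            results.append(res)
    return results


def sample_slice(sample: SliceSample, roi_mask: np.ndarray, spec: CropSpec,
                 strategy: str, seed: int = 0, *,
                 label: str = "unlabeled", case_id: str = "") -> List[CropResult]:
    """Dispatch to the requested sampling strategy."""
    roi = roi_stats(roi_mask, sample.grid)
    if strategy == "center":
        return center_crop(sample, roi_mask, spec, roi,
                           label=label, case_id=case_id)
    if strategy == "random":
        return random_crop(sample, roi_mask, spec, seed, roi,
                           label=label, case_id=case_id)
    if strategy == "stride":
        return stride_crop(sample, roi_mask, spec, roi,
                           label=label, case_id=case_id)
    raise ValueError(f"unknown strategy {strategy!r}")
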