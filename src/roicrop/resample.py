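"""Resampling of slices to a chosen target pixel spacing.

Intensity images are interpolated with a cubic B-spline; segmentation
masks use nearest-neighbor interpolation so they stay strictly binary.
Resampling is delegated to SimpleITK.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import SimpleITK as sitk

from .core import Grid2D, SliceSample, round_half_away

INTENSITY_INTERP = "bspline3"
MASK_INTERP = "nearest"


@dataclass(frozen=True)
class ResamplePlan:
    """Source and target grids of one resampling operation.

    The target grid is sized so the physical extent of the slice is
    preserved to within half a target pixel per axis.
    """

    source_grid: Grid2D
    target_grid: Grid2D

    @property
    def is_identity(self) -> bool:
        return (self.source_grid.shape == self.target_grid.shape
                and self.source_grid.spacing == self.target_grid.spacing)


def plan_resample(source: Grid2D,
                  target_spacing_mm: Tuple[float, float]) -> ResamplePlan:
    """Plan a resampling from ``source`` to the given target spacing.

    Target dimensions are the physical extent divided by the target
    spacing, rounded half away from zero, with a floor of one pixel.
    """
    sr, sc = target_spacing_mm
    if not (np.isfinite(sr) and sr > 0 and np.isfinite(sc) and sc > 0):
        raise ValueError(f"target spacing must be positive, got {target_spacing_mm}")
    ext_r, ext_c = source.extent_mm
    h = max(1, round_half_away(ext_r / sr))
    w = max(1, round_half_away(ext_c / sc))
    target = Grid2D(h, w, float(sr), float(sc))
    return ResamplePlan(source, target)


def _to_sitk(raster: np.ndarray, grid: Grid2D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(raster))
    # SimpleITK spacing order is (x, y) == (col, row)
    img.SetSpacing((grid.spacing_col_mm, grid.spacing_row_mm))
    return img


def _resample(raster: np.ndarray, plan: ResamplePlan,
              interpolator: int, dtype) -> np.ndarray:
    src = _to_sitk(raster.astype(np.float64), plan.source_grid)
    tgt = plan.target_grid
    out = sitk.Resample(
        src,
        size=(tgt.width_px, tgt.height_px),
        transform=sitk.Transform(),
        interpolator=interpolator,
        outputOrigin=src.GetOrigin(),
        outputSpacing=(tgt.spacing_col_mm, tgt.spacing_row_mm),
        outputDirection=src.GetDirection(),
        defaultPixelValue=0.0,
    )
    return sitk.GetArrayFromImage(out).astype(dtype)


def resample_intensity(sample: SliceSample, plan: ResamplePlan) -> np.ndarray:
    """Resample an intensity raster onto the plan's target grid.

    Uses cubic B-spline interpolation; samples falling outside the source
    domain take the boundary-extension value 0.  Values are not clipped,
    so B-spline overshoot near sharp edges is retained.
    """
    if sample.grid != plan.source_grid:
        raise ValueError("plan source grid does not match the slice grid")
    if plan.is_identity:
        return sample.intensity.copy()
    return _resample(sample.intensity, plan, sitk.sitkBSpline, np.float64)


def resample_mask(mask: np.ndarray, plan: ResamplePlan) -> np.ndarray:
    """Resample a binary mask with nearest-neighbor interpolation.

    Output is strictly binary (uint8 in {0, 1}).
    """
    if mask.shape != plan.source_grid.shape:
        raise ValueError("mask shape does not match the plan's source grid")
    if plan.is_identity:
        return mask.astype(np.uint8, copy=True)
    out = _resample(mask, plan, sitk.sitkNearestNeighbor, np.float64)
    return (out > 0.5).astype(np.uint8)


def resample_slice(sample: SliceSample, plan: ResamplePlan) -> SliceSample:
    """Resample a full slice (intensity plus any masks) onto the target grid."""
    return SliceSample(
        grid=plan.target_grid,
        intensity=resample_intensity(sample, plan),
        gland_mask=(None if sample.gland_mask is None
                    else resample_mask(sample.gland_mask, plan)),
        lesion_mask=(None if sample.lesion_mask is None
                     else resample_mask(sample.lesion_mask, plan)),
        slice_index=sample.slice_index,
    )
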