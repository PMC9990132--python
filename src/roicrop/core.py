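"""Shared geometric and case-level domain types.

Coordinate conventions obeyed by every module in this package:

* arrays are indexed 0-based, in (row, col) order, row-major;
* boxes are half-open: ``[top, top + height) x [left, left + width)``;
* physical pixel spacing is expressed in mm per pixel, always in
  (row, col) axis order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np

VALID_STATUSES = ("positive", "negative", "unknown")
VALID_LABELS = ("positive", "negative", "unlabeled")
VALID_STRATEGIES = ("center", "random", "stride")
VALID_SPLITS = ("train", "val", "test", "unassigned")


def round_half_away(x: float) -> int:
    """Round to nearest integer with exact halves going away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


class Box(NamedTuple):
    """Half-open integer box: rows [top, top+height), cols [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width


@dataclass(frozen=True)
class Grid2D:
    """A slice's pixel lattice: raster shape plus physical pixel spacing.

    Parameters
    ----------
    height_px, width_px
        Raster dimensions (rows, columns); both at least 1.
    spacing_row_mm, spacing_col_mm
        Physical size of one pixel along each axis, in mm; strictly
        positive and finite.
    """

    height_px: int
    width_px: int
    spacing_row_mm: float
    spacing_col_mm: float

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError(f"grid dimensions must be >= 1, got "
                             f"{self.height_px}x{self.width_px}")
        for name in ("spacing_row_mm", "spacing_col_mm"):
            s = getattr(self, name)
            if not (np.isfinite(s) and s > 0):
                raise ValueError(f"{name} must be positive and finite, got {s}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.height_px, self.width_px)

    @property
    def spacing(self) -> Tuple[float, float]:
        return (self.spacing_row_mm, self.spacing_col_mm)

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_row_mm * self.spacing_col_mm

    @property
    def extent_mm(self) -> Tuple[float, float]:
        """Physical size of the full raster, (rows, cols), in mm."""
        return (self.height_px * self.spacing_row_mm,
                self.width_px * self.spacing_col_mm)


def _check_binary(mask: np.ndarray, name: str) -> None:
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:10]}")


@dataclass
class SliceSample:
    """One intensity slice with aligned binary mask(s) on a shared grid."""

    grid: Grid2D
    intensity: np.ndarray
    gland_mask: Optional[np.ndarray] = None
    lesion_mask: Optional[np.ndarray] = None
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.intensity.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid "
                f"{self.grid.shape}")
        for name in ("gland_mask", "lesion_mask"):
            m = getattr(self, name)
            if m is None:
                continue
            if m.shape != self.grid.shape:
                raise ValueError(f"{name} shape {m.shape} does not match grid "
                                 f"{self.grid.shape}")
            _check_binary(m, name)


@dataclass(frozen=True)
class ROIStats:
    """Whole-slice statistics of a binary ROI mask.

    ``centroid_rc`` and ``tight_box`` are ``None`` when the mask is empty.
    The centroid is the arithmetic mean of the positive pixels' integer
    coordinates (pixel centers).
    """

    n_roi_px: int
    area_mm2: float
    centroid_rc: Optional[Tuple[float, float]]
    tight_box: Optional[Box]


def roi_stats(mask: np.ndarray, grid: Grid2D) -> ROIStats:
    """Count, physical area, centroid and tight bounding box of ``mask == 1``.

    Raises
    ------
    ValueError
        If the mask shape does not match the grid.
    """
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid "
                         f"{grid.shape}")
    rows, cols = np.nonzero(mask)
    n = int(rows.size)
    area = n * grid.pixel_area_mm2
    if n == 0:
        return ROIStats(0, 0.0, None, None)
    top, bottom = int(rows.min()), int(rows.max())
    left, right = int(cols.min()), int(cols.max())
    centroid = (float(rows.mean()), float(cols.mean()))
    box = Box(top, left, bottom - top + 1, right - left + 1)
    return ROIStats(n, area, centroid, box)


@dataclass(frozen=True)
class CropSpec:
    """Output patch geometry, sampling strategy and sampling constants.

    Parameters
    ----------
    out_h_px, out_w_px
        Patch size in pixels (on the resampled grid).
    target_spacing_mm
        Pixel spacing the slice is resampled to before sampling, (row, col).
    strategy
        One of ``center``, ``random``, ``stride``.
    c_random
        Oversampling factor for random cropping; the sample budget is
        ``floor(n_roi_px / n_crop_px * c_random)``.
    c_stride
        Step, in pixels, between consecutive stride-crop windows.
    c_min_area_mm2
        Minimum in-crop ROI area a patch must strictly exceed to be kept.
    max_redraw_factor
        Random cropping redraws rejected candidates up to
        ``max_redraw_factor * budget`` times before giving up.
    """

    out_h_px: int
    out_w_px: int
    target_spacing_mm: Tuple[float, float]
    strategy: str = "stride"
    c_random: float = 12.0
    c_stride: int = 32
    c_min_area_mm2: float = 0.0
    max_redraw_factor: int = 10

    def __post_init__(self) -> None:
        if self.out_h_px < 1 or self.out_w_px < 1:
            raise ValueError("output patch dimensions must be >= 1")
        if self.strategy not in VALID_STRATEGIES:
            raise ValueError(f"strategy must be one of {VALID_STRATEGIES}, "
                             f"got {self.strategy!r}")
        if self.c_random <= 0:
            raise ValueError("c_random must be positive")
        if self.c_stride < 1:
            raise ValueError("c_stride must be a positive integer")
        if self.c_min_area_mm2 < 0:
            raise ValueError("c_min_area_mm2 must be nonnegative")
        if self.max_redraw_factor < 1:
            raise ValueError("max_redraw_factor must be a positive integer")
        if any(s <= 0 or not np.isfinite(s) for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive and finite")

    @property
    def n_crop_px(self) -> int:
        """Number of pixels in one output patch."""
        return self.out_h_px * self.out_w_px


@dataclass
class CropResult:
    """One extracted patch with provenance."""

    patch: np.ndarray
    origin_rc: Tuple[int, int]
    grid: Grid2D
    in_crop_roi_area_mm2: float
    label: str
    case_id: str
    slice_index: int
    strategy: str
    padded: bool = False

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")
        if self.patch.shape != self.grid.shape:
            raise ValueError("patch shape must match its grid")


@dataclass
class CaseRecord:
    """One case: identity, health status, file references, split assignment."""

    case_id: str
    status: str
    image_path: str = ""
    gland_mask_path: str = ""
    lesion_mask_path: Optional[str] = None
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValueError(f"status must be one of {VALID_STATUSES}, "
                             f"got {self.status!r}")
        if self.split not in VALID_SPLITS:
            raise ValueError(f"split must be one of {VALID_SPLITS}")
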