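"""Slice and patch selection rules.

Covers the minimum-ROI-area filter, apex/base slice exclusion,
lesion-gland overlap retention, and the health-status routing that
decides which mask drives sampling, which label the patches carry, and
which area threshold applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np

from .core import CaseRecord, Grid2D, SliceSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionPolicy:
    """Selection thresholds and slice-exclusion switches.

    Parameters
    ----------
    c_min_area_neg_mm2
        Minimum in-crop gland area for negative/unknown cases
        (default 100 mm² = 1 cm²).
    c_min_area_pos_mm2
        Minimum in-crop lesion area for positive cases
        (default 20 mm² = 0.2 cm²).
    lesion_overlap_min
        A lesion mask is retained only when at least this fraction of its
        pixels lies inside the gland mask (default 0.5).
    exclude_end_slices
        Drop the first (apex) and last (base) gland-bearing slices.
    """

    c_min_area_neg_mm2: float = 100.0
    c_min_area_pos_mm2: float = 20.0
    lesion_overlap_min: float = 0.5
    exclude_end_slices: bool = True

    def __post_init__(self) -> None:
        if self.c_min_area_neg_mm2 < 0 or self.c_min_area_pos_mm2 < 0:
            raise ValueError("area thresholds must be nonnegative")
        if not 0.0 <= self.lesion_overlap_min <= 1.0:
            raise ValueError("lesion_overlap_min must lie in [0, 1]")


def passes_min_area(in_crop_roi_px: int, grid: Grid2D,
                    c_min_area_mm2: float) -> bool:
    """Strict minimum-area test: threshold < pixels x pixel area.

    A patch whose in-crop ROI area equals the threshold exactly is
    rejected.
    """
    return c_min_area_mm2 < in_crop_roi_px * grid.pixel_area_mm2


def select_slices(volume: Sequence[SliceSample],
                  policy: SelectionPolicy) -> List[int]:
    """Indices of gland-bearing slices, minus apex and base when excluded.

    With end-slice exclusion on, the first and last gland-bearing slices
    are dropped; if two or fewer slices bear gland, nothing remains.
    """
    gland_idx = [s.slice_index for s in volume
                 if s.gland_mask is not None and s.gland_mask.any()]
    if not policy.exclude_end_slices:
        return gland_idx
    if len(gland_idx) <= 2:
        return []
    return gland_idx[1:-1]


def lesion_overlap_fraction(lesion_mask: np.ndarray,
                            gland_mask: np.ndarray) -> float:
    """Fraction of lesion pixels lying inside the gland mask.

    This is a fraction of the *lesion*, never of the gland; an empty
    lesion gives 0.
    """
    if lesion_mask.shape != gland_mask.shape:
        raise ValueError(f"mask shapes differ: {lesion_mask.shape} vs "
                         f"{gland_mask.shape}")
    n_lesion = int(np.count_nonzero(lesion_mask))
    if n_lesion == 0:
        return 0.0
    n_inside = int(np.count_nonzero((lesion_mask > 0) & (gland_mask > 0)))
    return n_inside / n_lesion


class RoutedROI(NamedTuple):
    mask: np.ndarray
    label: str
    c_min_area_mm2: float


def route_roi(case: CaseRecord, sample: SliceSample,
              policy: SelectionPolicy) -> Optional[RoutedROI]:
    """Choose the sampling mask, label and area threshold for one slice.

    positive -> lesion mask (retained only if its gland-overlap fraction
    meets ``lesion_overlap_min``), label ``positive``, lesion threshold;
    negative -> gland mask, label ``negative``, gland threshold;
    unknown -> gland mask, label ``unlabeled``, gland threshold.

    Returns ``None`` when the required mask is absent (logged warning) or
    the routed mask is empty on this slice: such slices yield no samples.
    """
    if case.status == "positive":
        if sample.lesion_mask is None:
            logger.warning("case %s slice %d: positive case without lesion "
                           "mask, slice skipped", case.case_id,
                           sample.slice_index)
            return None
        if not sample.lesion_mask.any():
            return None
        if sample.gland_mask is not None:
            frac = lesion_overlap_fraction(sample.lesion_mask,
                                           sample.gland_mask)
            if frac < policy.lesion_overlap_min:
                logger.info("case %s slice %d: lesion discarded "
                            "(gland overlap %.2f < %.2f)", case.case_id,
                            sample.slice_index, frac,
                            policy.lesion_overlap_min)
                return None
        return RoutedROI(sample.lesion_mask, "positive",
                         policy.c_min_area_pos_mm2)
    if sample.gland_mask is None:
        logger.warning("case %s slice %d: gland mask missing, slice skipped",
                       case.case_id, sample.slice_index)
        return None
    if not sample.gland_mask.any():
        return None
    label = "negative" if case.status == "negative" else "unlabeled"
    return RoutedROI(sample.gland_mask, label, policy.c_min_area_neg_mm2)
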