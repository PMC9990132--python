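"""Reading volumes with spacing metadata; writing patches and manifests.

Input formats: NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd), read
through SimpleITK with the axis order normalized to (slice, row, col).
Output patches are written as NIfTI (lossless, spacing preserved) or
16-bit PNG (min-max scaled, with the scale recorded by the caller in the
manifest).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Set, Tuple

import numpy as np
import SimpleITK as sitk
from PIL import Image

from .core import CropResult

logger = logging.getLogger(__name__)

SUPPORTED_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")
PATCH_FORMATS = ("nifti", "png16")


@dataclass
class VolumeHandle:
    """A slice stack with physical spacing metadata.

    ``stack`` has shape (slices, rows, cols); ``spacing_mm`` is
    (row, col, slice) in mm.
    """

    stack: np.ndarray
    spacing_mm: Tuple[float, float, float]
    source_format: str = ""
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.stack.ndim != 3 or self.stack.size == 0:
            raise ValueError("stack must be a nonempty 3D array "
                             "(slices, rows, cols)")
        if any(s <= 0 or not np.isfinite(s) for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def n_slices(self) -> int:
        return self.stack.shape[0]


def _format_tag(path: str) -> str:
    lower = path.lower()
    for ext in SUPPORTED_EXTS:
        if lower.endswith(ext):
            return ext
    raise IOError(f"unsupported volume format: {path} "
                  f"(expected one of {SUPPORTED_EXTS})")


def read_volume(path: str, case_id: str = "") -> VolumeHandle:
    """Read a NIfTI or MetaImage volume, normalizing axes to (slice, row, col).

    2D images are promoted to single-slice stacks.  Spacing is taken from
    the file header and mapped to (row, col, slice) order.
    """
    tag = _format_tag(path)
    if not os.path.exists(path):
        raise IOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    sp = img.GetSpacing()  # (x, y[, z]) == (col, row[, slice])
    if arr.ndim == 2:
        arr = arr[None]
        spacing = (float(sp[1]), float(sp[0]), 1.0)
    elif arr.ndim == 3:
        spacing = (float(sp[1]), float(sp[0]), float(sp[2]))
    else:
        raise IOError(f"{path}: expected a 2D or 3D volume, got {arr.ndim}D")
    return VolumeHandle(arr, spacing, source_format=tag, case_id=case_id)


def read_mask_volume(path: str, case_id: str = "") -> VolumeHandle:
    """Read a segmentation volume, binarizing any nonzero value to 1."""
    vol = read_volume(path, case_id)
    vals = np.unique(vol.stack)
    if not np.isin(vals, (0, 1)).all():
        logger.warning("%s: mask values %s binarized (>0 -> 1)", path,
                       vals[:10])
    vol.stack = (vol.stack > 0).astype(np.uint8)
    return vol


def write_volume(stack: np.ndarray,
                 spacing_mm: Tuple[float, float, float], path: str) -> str:
    """Write a (slice, row, col) stack with (row, col, slice) spacing."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(stack))
    img.SetSpacing((spacing_mm[1], spacing_mm[0], spacing_mm[2]))
    sitk.WriteImage(img, path)
    return path


def patch_filename(result: CropResult, fmt: str) -> str:
    ext = ".nii.gz" if fmt == "nifti" else ".png"
    return (f"{result.case_id}_s{result.slice_index:03d}_{result.strategy}"
            f"_r{result.origin_rc[0]}_c{result.origin_rc[1]}{ext}")


class PatchWriter:
    """Writes patches into one output directory without silent clobbering.

    Within one writer's lifetime, a filename collision (two patches with
    identical provenance coordinates, e.g. duplicate random draws) gets a
    ``_kN`` suffix instead of overwriting.
    """

    def __init__(self, out_dir: str, fmt: str = "nifti") -> None:
        if fmt not in PATCH_FORMATS:
            raise ValueError(f"format must be one of {PATCH_FORMATS}")
        self.out_dir = out_dir
        self.fmt = fmt
        self._seen: Set[str] = set()
        os.makedirs(out_dir, exist_ok=True)

    def write(self, result: CropResult) -> Tuple[str, Optional[Tuple[float, float]]]:
        """Write one patch; returns (path, png scale or None).

        For png16 the scale is the (min, max) of the patch used for the
        16-bit min-max rescaling; a constant patch gets the degenerate
        scale (min, min) and is written as zeros.
        """
        name = patch_filename(result, self.fmt)
        if name in self._seen:
            k = 1
            stem, ext = (name.split(".", 1) + [""])[:2]
            while f"{stem}_k{k}.{ext}" in self._seen:
                k += 1
            name = f"{stem}_k{k}.{ext}"
        self._seen.add(name)
        path = os.path.join(self.out_dir, name)
        if self.fmt == "nifti":
            img = sitk.GetImageFromArray(
                np.ascontiguousarray(result.patch.astype(np.float64)))
            img.SetSpacing((result.grid.spacing_col_mm,
                            result.grid.spacing_row_mm))
            sitk.WriteImage(img, path)
            return path, None
        lo = float(result.patch.min())
        hi = float(result.patch.max())
        if hi > lo:
            scaled = (result.patch - lo) / (hi - lo) * 65535.0
        else:
            scaled = np.zeros_like(result.patch, dtype=np.float64)
        Image.fromarray(np.round(scaled).astype(np.uint16)).save(path)
        return path, (lo, hi)


def read_patch(path: str) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Read back a NIfTI patch as (raster, (row, col) spacing in mm)."""
    img = sitk.ReadImage(path)
    arr = sitk.GetArrayFromImage(img)
    arr = np.squeeze(arr)
    sp = img.GetSpacing()
    return arr, (float(sp[1]), float(sp[0]))
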