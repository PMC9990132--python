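"""Synthetic prostate-like phantoms for end-to-end testing without data.

A phantom case is a slice stack holding an elliptical "gland" whose
per-slice area tapers toward the first (apex) and last (base) gland
slices, optional disk-shaped "lesions" placed inside or straddling the
gland, a smooth intensity background with gland/lesion contrast, and
additive Gaussian noise (a magnitude approximation of MR noise; geometry,
not physics, is what these phantoms exercise).

Cohorts emulate the heterogeneity of multi-center T2-weighted prostate
MRI: square image sizes from 256 to 1024 px, in-plane pixel spacing from
0.2 to 0.8 mm (jointly constrained to a realistic pelvic field of view),
off-center glands, and varying gland size.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import CaseRecord
from .io import VolumeHandle, write_volume


@dataclass(frozen=True)
class LesionSpec:
    """One disk lesion.

    ``center_offset_frac`` positions the lesion center relative to the
    gland center, in units of the gland semi-axes (so (0.5, 0) is halfway
    out along the row axis).  ``inside_gland`` asserts the disk fits
    entirely inside the gland ellipse (validated); a straddling lesion is
    placed so it crosses the gland border.  ``slice_range`` restricts the
    lesion to slices [start, stop) of the stack; None means all gland
    slices.
    """

    center_offset_frac: Tuple[float, float] = (0.0, 0.0)
    radius_mm: float = 6.0
    inside_gland: bool = True
    slice_range: Optional[Tuple[int, int]] = None


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case."""

    image_px: int = 384
    spacing_mm: float = 0.5
    n_slices: int = 12
    gland_center_offset_frac: Tuple[float, float] = (0.0, 0.0)
    gland_semi_axes_mm: Tuple[float, float] = (20.0, 25.0)
    gland_slice_range: Optional[Tuple[int, int]] = None
    lesions: Tuple[LesionSpec, ...] = ()
    noise_sigma: float = 5.0
    status: str = "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.2 <= self.spacing_mm <= 0.8:
            raise ValueError("spacing_mm must lie in [0.2, 0.8]")
        if not 256 <= self.image_px <= 1024:
            raise ValueError("image_px must lie in [256, 1024]")
        if self.n_slices < 3:
            raise ValueError("need at least 3 slices")
        if any(a <= 0 for a in self.gland_semi_axes_mm):
            raise ValueError("gland semi-axes must be positive")
        if any(l.radius_mm <= 0 for l in self.lesions):
            raise ValueError("lesion radii must be positive")


def _ellipse_mask(shape: Tuple[int, int], center_rc: Tuple[float, float],
                  semi_axes_px: Tuple[float, float]) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - center_rc[0]
    cc = np.arange(shape[1])[None, :] - center_rc[1]
    ar, ac = semi_axes_px
    return ((rr / ar) ** 2 + (cc / ac) ** 2 <= 1.0).astype(np.uint8)


def _gland_slice_indices(spec: PhantomSpec) -> List[int]:
    if spec.gland_slice_range is not None:
        lo, hi = spec.gland_slice_range
        idx = list(range(max(0, lo), min(spec.n_slices, hi)))
    else:
        # leave one empty slice at each end when the stack allows it
        if spec.n_slices >= 5:
            idx = list(range(1, spec.n_slices - 1))
        else:
            idx = list(range(spec.n_slices))
    if len(idx) < 3:
        raise ValueError("gland must span at least 3 slices")
    return idx


def _taper_profile(n: int) -> np.ndarray:
    """Per-slice semi-axis scale, peaking mid-gland, small at apex/base."""
    t = np.linspace(-1.0, 1.0, n)
    return 0.3 + 0.7 * np.sqrt(np.clip(1.0 - t ** 2, 0.04, 1.0))


def generate_case(spec: PhantomSpec, out_dir: Optional[str] = None
                  ) -> Tuple[VolumeHandle, VolumeHandle,
                             Optional[VolumeHandle], CaseRecord]:
    """Generate one phantom case; optionally write its NIfTI files.

    Returns (image, gland mask, lesion mask or None, case record).  Fully
    determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, side, sp = spec.n_slices, spec.image_px, spec.spacing_mm
    shape = (side, side)
    gland_center = (side / 2 * (1 + spec.gland_center_offset_frac[0]),
                    side / 2 * (1 + spec.gland_center_offset_frac[1]))
    semi_px = (spec.gland_semi_axes_mm[0] / sp,
               spec.gland_semi_axes_mm[1] / sp)

    gland_idx = _gland_slice_indices(spec)
    taper = _taper_profile(len(gland_idx))

    gland = np.zeros((n, side, side), dtype=np.uint8)
    for k, z in enumerate(gland_idx):
        gland[z] = _ellipse_mask(shape, gland_center,
                                 (semi_px[0] * taper[k], semi_px[1] * taper[k]))

    lesion: Optional[np.ndarray] = None
    if spec.lesions:
        lesion = np.zeros_like(gland)
        for les in spec.lesions:
            r_px = les.radius_mm / sp
            if les.inside_gland:
                min_axis = min(spec.gland_semi_axes_mm)
                if les.radius_mm >= min_axis:
                    raise ValueError(
                        f"lesion radius {les.radius_mm} mm cannot fit inside "
                        f"gland with semi-axes {spec.gland_semi_axes_mm} mm")
            center = (gland_center[0] + les.center_offset_frac[0] * semi_px[0],
                      gland_center[1] + les.center_offset_frac[1] * semi_px[1])
            zlo, zhi = les.slice_range if les.slice_range is not None else (
                gland_idx[0], gland_idx[-1] + 1)
            for z in range(max(0, zlo), min(n, zhi)):
                disk = _ellipse_mask(shape, center, (r_px, r_px))
                if les.inside_gland:
                    disk &= gland[z]
                lesion[z] |= disk

    # smooth background gradient + tissue contrast + noise
    rr = np.linspace(0, 1, side)[:, None]
    cc = np.linspace(0, 1, side)[None, :]
    background = 80.0 + 40.0 * rr + 20.0 * cc
    image = np.broadcast_to(background, (n, side, side)).astype(np.float64).copy()
    image += 60.0 * gland
    if lesion is not None:
        image -= 35.0 * lesion
    image += rng.normal(0.0, spec.noise_sigma, size=image.shape)

    spacing3 = (sp, sp, 3.0)  # through-plane spacing carried, never resampled
    case_id = f"phantom_{spec.status[:3]}_{spec.seed:06d}"
    img_h = VolumeHandle(image, spacing3, case_id=case_id)
    gland_h = VolumeHandle(gland, spacing3, case_id=case_id)
    lesion_h = (VolumeHandle(lesion, spacing3, case_id=case_id)
                if lesion is not None else None)

    record = CaseRecord(case_id=case_id, status=spec.status)
    if out_dir is not None:
        case_dir = os.path.join(out_dir, case_id)
        os.makedirs(case_dir, exist_ok=True)
        record.image_path = write_volume(
            image, spacing3, os.path.join(case_dir, "image.nii.gz"))
        record.gland_mask_path = write_volume(
            gland, spacing3, os.path.join(case_dir, "gland.nii.gz"))
        if lesion is not None:
            record.lesion_mask_path = write_volume(
                lesion, spacing3, os.path.join(case_dir, "lesion.nii.gz"))
    return img_h, gland_h, lesion_h, record


# image sizes sampled for cohorts; spacing is then constrained so the
# field of view (size x spacing) stays within a realistic pelvic range
_COHORT_SIZES = (256, 320, 384, 512, 640, 768, 1024)
_FOV_MM = (100.0, 240.0)


def _jitter_spec(base: PhantomSpec, status: str, seed: int,
                 rng: np.random.Generator) -> PhantomSpec:
    side = int(rng.choice(_COHORT_SIZES))
    sp_lo = max(0.2, _FOV_MM[0] / side)
    sp_hi = min(0.8, _FOV_MM[1] / side)
    spacing = round(float(rng.uniform(sp_lo, sp_hi)), 3)
    offset = tuple(float(rng.uniform(-0.15, 0.15)) for _ in range(2))
    axes = (float(rng.uniform(14.0, 24.0)), float(rng.uniform(17.0, 28.0)))
    lesions: Tuple[LesionSpec, ...] = ()
    if status == "positive":
        lesions = (LesionSpec(
            center_offset_frac=(float(rng.uniform(-0.4, 0.4)),
                                float(rng.uniform(-0.4, 0.4))),
            radius_mm=float(rng.uniform(4.0, 8.0)),
            inside_gland=True,
        ),)
    return replace(base, image_px=side, spacing_mm=spacing,
                   gland_center_offset_frac=offset,
                   gland_semi_axes_mm=axes, lesions=lesions,
                   status=status, seed=seed)


def generate_cohort(n_pos: int, n_neg: int,
                    base_spec: Optional[PhantomSpec] = None,
                    seed: int = 0,
                    out_dir: Optional[str] = None) -> List[Tuple[PhantomSpec, CaseRecord]]:
    """Generate a cohort of phantom cases with jittered geometry.

    Per-case parameters are drawn from a generator seeded with ``seed``;
    the cohort is fully deterministic.  When ``out_dir`` is given, each
    case is written as a NIfTI folder consumable by the readers.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("cohort counts must be nonnegative")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    out: List[Tuple[PhantomSpec, CaseRecord]] = []
    statuses = ["positive"] * n_pos + ["negative"] * n_neg
    for i, status in enumerate(statuses):
        case_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = _jitter_spec(base, status, case_seed, rng)
        _, _, _, record = generate_case(spec, out_dir=out_dir)
        out.append((spec, record))
    return out


def write_case_table(cases: Sequence[CaseRecord], path: str) -> str:
    """Write the cohort case table (CSV) consumed by the crop pipeline."""
    import pandas as pd

    rows = [{"case_id": c.case_id, "status": c.status,
             "image_path": c.image_path, "gland_mask_path": c.gland_mask_path,
             "lesion_mask_path": c.lesion_mask_path or ""} for c in cases]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
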