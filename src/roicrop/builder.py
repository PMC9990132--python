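"""Per-case pipeline orchestration and dataset assembly.

Runs load -> resample -> select -> sample -> filter -> write for every
case, assigns train/val/test splits per class, balances labels by
undersampling negatives, and records every emitted patch in a manifest.

Training uses the configured sampling strategy with the health-status
routing (positives sample the lesion mask); validation and test are
always stride-sampled over the gland ROI of both statuses, with the same
stride and the per-status area thresholds, so the whole gland is covered
at evaluation.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CaseRecord, CropResult, CropSpec, Grid2D, SliceSample
from .io import PatchWriter, read_mask_volume, read_volume
from .resample import plan_resample, resample_slice
from .sampler import sample_slice
from .selection import SelectionPolicy, route_roi, select_slices

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "case_id", "status", "split", "slice_index", "strategy",
    "origin_row", "origin_col", "crop_h_px", "crop_w_px",
    "spacing_row_mm", "spacing_col_mm", "label", "in_crop_roi_area_mm2",
    "padded", "scale_min", "scale_max", "path",
]


@dataclass(frozen=True)
class SplitPlan:
    """Per-class random train/val/test split.

    Val and test each take the nearest integer to their fraction of the
    class size, with exact halves rounded down; the remainder goes to
    train.  Assignment is random under ``seed`` and deterministic.
    """

    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    per_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be nonnegative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _round_half_down(x: float) -> int:
    """Nearest integer with exact halves rounded down."""
    return int(math.ceil(x - 0.5))


def split_cases(cases: Sequence[CaseRecord], plan: SplitPlan) -> List[CaseRecord]:
    """Assign each case to train/val/test, per class when ``per_class``."""
    groups: Dict[str, List[CaseRecord]] = {}
    if plan.per_class:
        for c in cases:
            groups.setdefault(c.status, []).append(c)
    else:
        groups["all"] = list(cases)
    rng = np.random.default_rng(plan.seed)
    _, f_val, f_test = plan.fractions
    for key in sorted(groups):
        members = groups[key]
        n = len(members)
        if n < 3:
            if n and (f_val > 0 or f_test > 0):
                logger.warning("class %r has only %d case(s); all assigned "
                               "to train", key, n)
            for c in members:
                c.split = "train"
            continue
        n_val = _round_half_down(f_val * n)
        n_test = _round_half_down(f_test * n)
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            if pos < n_val:
                members[idx].split = "val"
            elif pos < n_val + n_test:
                members[idx].split = "test"
            else:
                members[idx].split = "train"
    return list(cases)


def _volume_slices(case: CaseRecord) -> Tuple[List[SliceSample], Grid2D]:
    image = read_volume(case.image_path, case.case_id)
    gland = read_mask_volume(case.gland_mask_path, case.case_id)
    lesion = (read_mask_volume(case.lesion_mask_path, case.case_id)
              if case.lesion_mask_path else None)
    sr, sc, _ = image.spacing_mm
    grid = Grid2D(image.stack.shape[1], image.stack.shape[2], sr, sc)
    slices = []
    for z in range(image.n_slices):
        slices.append(SliceSample(
            grid=grid,
            intensity=image.stack[z].astype(np.float64),
            gland_mask=gland.stack[z],
            lesion_mask=None if lesion is None else lesion.stack[z],
            slice_index=z,
        ))
    return slices, grid


def _slice_seed(base_seed: int, case_index: int, slice_index: int) -> int:
    ss = np.random.SeedSequence([base_seed, case_index, slice_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _crop_case(case: CaseRecord, case_index: int, spec: CropSpec,
               policy: SelectionPolicy, seed: int,
               val_test_strategy: str = "stride") -> List[CropResult]:
    """All accepted patches of one case, after routing and selection."""
    try:
        slices, _ = _volume_slices(case)
    except IOError as exc:
        logger.error("case %s skipped: %s", case.case_id, exc)
        return []
    eligible = set(select_slices(slices, policy))
    is_eval = case.split in ("val", "test")
    strategy = val_test_strategy if is_eval else spec.strategy
    results: List[CropResult] = []
    for sample in slices:
        if sample.slice_index not in eligible:
            continue
        plan = plan_resample(sample.grid, spec.target_spacing_mm)
        if is_eval:
            # coverage sampling over the gland, per-status threshold
            if sample.gland_mask is None or not sample.gland_mask.any():
                continue
            mask_src = sample.gland_mask
            label = "positive" if case.status == "positive" else (
                "negative" if case.status == "negative" else "unlabeled")
            threshold = (policy.c_min_area_pos_mm2
                         if case.status == "positive"
                         else policy.c_min_area_neg_mm2)
        else:
            routed = route_roi(case, sample, policy)
            if routed is None:
                continue
            mask_src, label, threshold = routed
        # slice-level pregate: no crop can pass if the whole-slice ROI
        # area does not exceed the threshold
        slice_area = float(mask_src.sum()) * sample.grid.pixel_area_mm2
        if not slice_area > threshold:
            continue
        rs = resample_slice(sample, plan)
        roi_mask = (rs.gland_mask if mask_src is sample.gland_mask
                    else rs.lesion_mask)
        if roi_mask is None or not roi_mask.any():
            continue
        eff_spec = CropSpec(
            out_h_px=spec.out_h_px, out_w_px=spec.out_w_px,
            target_spacing_mm=spec.target_spacing_mm, strategy=strategy,
            c_random=spec.c_random, c_stride=spec.c_stride,
            c_min_area_mm2=threshold,
            max_redraw_factor=spec.max_redraw_factor)
        results.extend(sample_slice(
            rs, roi_mask, eff_spec, strategy,
            seed=_slice_seed(seed, case_index, sample.slice_index),
            label=label, case_id=case.case_id))
    return results


def build_dataset(cases: Sequence[CaseRecord], spec: CropSpec,
                  policy: SelectionPolicy, plan: Optional[SplitPlan] = None,
                  out_dir: Optional[str] = None, *,
                  val_test_strategy: str = "stride",
                  output_format: str = "nifti",
                  seed: int = 0) -> pd.DataFrame:
    """Run the full pipeline over a cohort and return the manifest.

    When ``out_dir`` is given, every patch is written there and the
    manifest's ``path`` column references the files; otherwise patches
    are not persisted and ``path`` is empty.
    """
    cases = list(cases)
    if plan is not None and any(c.split == "unassigned" for c in cases):
        split_cases(cases, plan)
    writer = PatchWriter(out_dir, output_format) if out_dir else None
    rows = []
    for i, case in enumerate(sorted(cases, key=lambda c: c.case_id)):
        for res in _crop_case(case, i, spec, policy, seed, val_test_strategy):
            path, scale = (writer.write(res) if writer else ("", None))
            if path:
                # manifests are portable: paths are relative to out_dir
                path = os.path.relpath(path, out_dir)
            rows.append({
                "case_id": res.case_id, "status": case.status,
                "split": case.split, "slice_index": res.slice_index,
                "strategy": res.strategy,
                "origin_row": res.origin_rc[0], "origin_col": res.origin_rc[1],
                "crop_h_px": res.grid.height_px, "crop_w_px": res.grid.width_px,
                "spacing_row_mm": res.grid.spacing_row_mm,
                "spacing_col_mm": res.grid.spacing_col_mm,
                "label": res.label,
                "in_crop_roi_area_mm2": res.in_crop_roi_area_mm2,
                "padded": res.padded,
                "scale_min": None if scale is None else scale[0],
                "scale_max": None if scale is None else scale[1],
                "path": path,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest.empty:
        logger.warning("build_dataset produced an empty manifest")
    return manifest


def balance_images(manifest: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Undersample negative rows to the positive row count.

    All positive rows are kept; negatives are subsampled without
    replacement.  If negatives are already the minority, the manifest is
    returned unchanged (with a warning).  Rows with other labels pass
    through untouched.
    """
    pos = manifest[manifest["label"] == "positive"]
    neg = manifest[manifest["label"] == "negative"]
    rest = manifest[~manifest["label"].isin(["positive", "negative"])]
    if len(neg) < len(pos):
        logger.warning("fewer negative (%d) than positive (%d) images; "
                       "keeping all negatives", len(neg), len(pos))
        return manifest.copy()
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    neg_kept = neg.iloc[np.sort(keep)]
    out = pd.concat([pos, neg_kept, rest]).sort_index()
    return out.reset_index(drop=True)


def summarize(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-(split, label) image counts; all zero cells present."""
    if manifest.empty:
        idx = pd.MultiIndex.from_product(
            [["train", "val", "test"], ["positive", "negative", "unlabeled"]],
            names=["split", "label"])
        return pd.DataFrame({"n_images": 0}, index=idx).reset_index()
    table = (manifest.groupby(["split", "label"]).size()
             .rename("n_images").reset_index())
    return table


def write_manifest(manifest: pd.DataFrame, path: str,
                   config: Optional[dict] = None) -> str:
    """Write the manifest CSV plus a JSON sidecar with the resolved config."""
    manifest.to_csv(path, index=False)
    if config is not None:
        sidecar = os.path.splitext(path)[0] + "_config.json"
        with open(sidecar, "w") as fh:
            json.dump(config, fh, indent=2, sort_keys=True, default=str)
    return path
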