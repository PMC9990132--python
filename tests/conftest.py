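import numpy as np
import pytest

from roicrop import CropSpec, Grid2D, PhantomSpec, SliceSample


def disk_mask(shape, center_rc, radius_px):
    rr = np.arange(shape[0])[:, None] - center_rc[0]
    cc = np.arange(shape[1])[None, :] - center_rc[1]
    return ((rr ** 2 + cc ** 2) <= radius_px ** 2).astype(np.uint8)


@pytest.fixture
def grid_05():
    return Grid2D(384, 384, 0.5, 0.5)


@pytest.fixture
def generous_slice(grid_05):
    """A slice whose ROI is a 100x100 square (exactly 10,000 pixels),
    comfortably inside the image."""
    mask = np.zeros(grid_05.shape, dtype=np.uint8)
    mask[142:242, 142:242] = 1
    intensity = np.linspace(0, 100, grid_05.width_px)[None, :].repeat(
        grid_05.height_px, axis=0)
    return SliceSample(grid=grid_05, intensity=intensity,
                       gland_mask=mask, slice_index=0), mask


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small written phantom cohort shared across tests (read-only)."""
    from roicrop import generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    cohort = generate_cohort(2, 3, seed=11, out_dir=str(out))
    return [rec for _, rec in cohort]


@pytest.fixture
def routing_phantom_spec():
    """Positive phantom: gland on 8 slices, lesion on exactly 2 of them."""
    from roicrop import LesionSpec

    return PhantomSpec(
        image_px=320, spacing_mm=0.5, n_slices=10,
        gland_slice_range=(1, 9),
        gland_semi_axes_mm=(20.0, 25.0),
        lesions=(LesionSpec(center_offset_frac=(0.1, -0.1), radius_mm=7.0,
                            inside_gland=True, slice_range=(4, 6)),),
        status="positive", seed=21)
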