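import numpy as np
import pytest

from orchardmap.raster_io import Affine, ParcelImage
from orchardmap.synthetic import OrchardScenario, generate_orchard


@pytest.fixture(scope="session")
def study_truth():
    """Noise-free study-layout scene: 10 rows x 25 trees, 2 m / 6 m spacing,
    crowns up to 3 m, 10% missing, 0.5 m/pixel."""
    return generate_orchard(OrchardScenario(noise_sd=0.0, seed=42))


@pytest.fixture(scope="session")
def small_truth():
    """Small noise-free scene for cheap per-stage tests."""
    return generate_orchard(
        OrchardScenario(n_rows=4, trees_per_row=8, noise_sd=0.0, seed=1))


def make_image(bands, resolution=0.5, nodata_mask=None, band_names=None,
               transform=None):
    bands = np.asarray(bands, dtype=np.float64)
    if band_names is None:
        band_names = ("blue", "green", "red", "nir")[:bands.shape[0]]
    if transform is None:
        transform = Affine.north_up(resolution, 0.0,
                                    bands.shape[1] * resolution)
    return ParcelImage(bands=bands, band_names=band_names,
                       resolution=resolution, transform=transform,
                       nodata_mask=nodata_mask)


def brute_force_box_count(mask: np.ndarray, window) -> int:
    """Independent per-pixel recount of canopy pixels inside a box window."""
    r0, r1, c0, c1 = window
    n = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if r0 <= r < r1 and c0 <= c < c1 and mask[r, c] == 1:
                n += 1
    return n
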