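import numpy as np
import pytest

from ctseqmtf import CTSlice, PhantomSpec


@pytest.fixture(scope="session")
def small_spec():
    """A 160x160 phantom that renders fast; top edge at row 44."""
    return PhantomSpec(image_size=(160, 160), center_px=(84.0, 80.0),
                       radii_px=(40.0, 70.0), psf_sigma_mm=0.5)


@pytest.fixture(scope="session")
def default_spec():
    """The default full-size phantom used for oracle measurements."""
    return PhantomSpec(psf_sigma_mm=0.5)


@pytest.fixture()
def flat_slice():
    """A uniform air slice (no object)."""
    return CTSlice(pixels=np.full((64, 64), -1000.0), pixel_spacing_mm=0.5)


def disc_slice(center, radius, shape=(64, 64), object_hu=120.0,
               background_hu=-1000.0, spacing=0.5):
    """Hard-edged disc rendered by center-inclusion (no anti-aliasing)."""
    rows, cols = np.indices(shape)
    inside = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius ** 2
    pixels = np.where(inside, object_hu, background_hu).astype(float)
    return CTSlice(pixels=pixels, pixel_spacing_mm=spacing)
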