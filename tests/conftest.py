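import numpy as np
import pytest

from ihcquant import RGBImage, SlideSpec, generate_slide


@pytest.fixture(scope="session")
def clean_slide():
    """A noiseless, jitter-free, non-overlapping default slide + truth."""
    return generate_slide(
        SlideSpec(seed=1, noise_sd=0.0, color_jitter_sd=0.0, max_overlap_fraction=0.0)
    )


@pytest.fixture(scope="session")
def small_slide():
    """A small noisy slide for fast end-to-end checks."""
    return generate_slide(
        SlideSpec(width=256, height=256, n_cells=12, positive_fraction=0.5, seed=7)
    )


@pytest.fixture
def blank_image():
    """A uniform pale background tile (no cells)."""
    px = np.empty((64, 64, 3), dtype=np.uint8)
    px[..., 0] = 242
    px[..., 1] = 238
    px[..., 2] = 232
    return RGBImage(px, pixel_size=0.46)
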