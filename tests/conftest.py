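import numpy as np
import pytest

from lignoquant.imagestack_io import ExposureStack, GreyImage


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def linear_stack(
    wall_mask: np.ndarray,
    gain: float,
    exposures=(500.0, 1000.0, 2000.0, 3000.0),
    floor: float = 2.0,
    pixel_size_um: float = 0.8,
) -> ExposureStack:
    """Tiny noise-free camera model: wall pixels at min(255, gain*e), lumen
    pixels at `floor`.  Shared by fluorometry and pipeline tests."""
    frames = []
    for e in exposures:
        img = np.full(wall_mask.shape, floor, dtype=np.float64)
        img[wall_mask] = min(255.0, gain * e)
        frames.append(GreyImage(np.round(img).astype(np.uint8), pixel_size_um))
    return ExposureStack(frames, list(exposures))


@pytest.fixture
def small_wall_mask():
    mask = np.zeros((32, 32), dtype=bool)
    mask[:, 10:14] = True
    mask[20:24, :] = True
    return mask
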