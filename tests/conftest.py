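import numpy as np
import pytest

from flowerseg.io_core import PixelCoord, RgbImage
from flowerseg.trainset import PatchManifest, PatchSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return RgbImage(rng.integers(0, 256, (48, 56, 3)).astype(np.uint8), id="rand")


def make_separable_manifest(n_per_class: int = 100, seed: int = 0) -> PatchManifest:
    """Bright vs dark 31x31 blocks — a linearly separable patch task."""
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_per_class):
        bright = rng.integers(200, 256, (31, 31, 3)).astype(np.uint8)
        dark = rng.integers(0, 56, (31, 31, 3)).astype(np.uint8)
        samples.append(PatchSample(bright, "positive", "bright", PixelCoord(15, 15)))
        samples.append(PatchSample(dark, "negative", "dark", PixelCoord(15, 15)))
    return PatchManifest(samples=samples, patch_size=31, seed=seed)
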