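import numpy as np
import pytest

from endotriage.masks import RegionClass
from endotriage.synthetic import DEFAULT_PALETTES, SyntheticSlideSpec, generate_slide


@pytest.fixture(scope="session")
def malignant_slide():
    """One partly malignant slide with blood, shared across tests."""
    spec = SyntheticSlideSpec(
        base_size=1536,
        n_tissue_pieces=4,
        fragmentation="large_pieces",
        malignant_fraction=0.5,
        blood_fraction=0.15,
        seed=7,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def benign_slide():
    spec = SyntheticSlideSpec(
        base_size=1536, n_tissue_pieces=3, malignant_fraction=0.0, seed=11
    )
    return generate_slide(spec)


def palette_image(name: str, shape, seed: int = 0) -> np.ndarray:
    """Raster drawn from one class palette (mean colour + Gaussian noise)."""
    mean, std = DEFAULT_PALETTES[name]
    rng = np.random.default_rng(seed)
    img = rng.normal(mean, std, size=(*shape, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def region_mask_small():
    """Hand-built 8x8 region mask covering all four classes."""
    m = np.full((8, 8), int(RegionClass.BACKGROUND), dtype=np.uint8)
    m[1:5, 1:5] = int(RegionClass.OTHER_BENIGN)
    m[2:4, 2:4] = int(RegionClass.MALIGNANT)
    m[6:8, 0:3] = int(RegionClass.BLOOD_MUCUS)
    return m
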