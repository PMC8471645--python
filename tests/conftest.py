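import numpy as np
import pytest

from maskrepro.mask_io import BinaryMask, LabelVolume
from maskrepro.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_labels(rng):
    """A small random zonal label volume with both labels present."""
    vox = rng.integers(0, 3, size=(6, 7, 8))
    vox[0, 0, 0], vox[1, 1, 1] = 1, 2  # guarantee both regions non-empty
    return LabelVolume(vox, (3.0, 0.5, 0.5), (1.0, -2.0, 3.5), "S000", "scan1", "manual")


def coarse_config(**overrides) -> SyntheticConfig:
    """Synthetic cohort at coarse in-plane spacing: same design, faster grids."""
    defaults = dict(
        n_subjects=5,
        spacing=(3.0, 1.5, 1.5),
        method_noise={"manual": 0.4, "vnet": 1.6},
        seed=11,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def random_mask(rng, shape=(8, 9, 10), p=0.3, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    vox = rng.random(shape) < p
    if not vox.any():
        vox[tuple(d // 2 for d in shape)] = True
    return BinaryMask(vox, spacing)
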