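import numpy as np
import pytest

from texturestager.preprocess import QuantizedROI
from texturestager.synthetic import CohortSpec, generate_cohort


def random_quantized_roi(rng, max_side=8, n_levels=4, ensure_pairs=True):
    """Small random level array + random mask wrapped as a QuantizedROI."""
    while True:
        h = rng.integers(2, max_side + 1)
        w = rng.integers(2, max_side + 1)
        levels = rng.integers(0, n_levels, size=(h, w))
        mask = rng.random((h, w)) < 0.8
        if mask.sum() < 2:
            continue
        roi = QuantizedROI.from_levels(levels, mask, n_levels)
        if not ensure_pairs:
            return roi
        # need at least one 4- or 8-neighbor pair inside the mask
        from texturestager.texture import ANGLE_OFFSETS, glcm

        if any(not glcm(roi, off).is_empty for off in ANGLE_OFFSETS.values()):
            return roi


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny strongly-separated cohort shared across tests (10 vs 10)."""
    spec = CohortSpec.with_effect("large", n_per_class=10, image_size=48, seed=7)
    return spec, generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
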