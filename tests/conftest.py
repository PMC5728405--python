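import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from splicexport import synthetic_data as sd


@pytest.fixture(scope="session")
def small_fish():
    """A small noiseless FISH field with ground truth, reused across tests."""
    spec = sd.FishImageSpec(
        image_shape=(384, 384), n_cells=5, true_nc_ratio=2.0, noise_sd=0.0, seed=11
    )
    return spec, *sd.generate_fish_image(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)
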