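from __future__ import annotations

import numpy as np
import pytest

from gdsaqa import synthetic_data as sd


@pytest.fixture(scope="session")
def small_reference():
    """A small noise-free plateau composite shared by closed-form tests."""
    config = sd.ScenarioConfig(scenario="stable", n_fractions=2, image_size=96)
    return sd.make_reference_composite(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)
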