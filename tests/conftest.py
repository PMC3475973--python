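import numpy as np
import pytest

from tkcd import ModelParams, run_preset

REFERENCE_D = (0.1, 0.11, 0.2, 0.9, 1.0)


@pytest.fixture(scope="session")
def params():
    """Reference demography: b = 10, five classes, 100-cell baseline."""
    return ModelParams(10.0, REFERENCE_D)


@pytest.fixture(scope="session")
def preset_trajectories():
    """The three built-in constant-exposure runs, integrated once."""
    return {name: run_preset(name) for name in ("low", "moderate", "high")}


@pytest.fixture
def rng():
    return np.random.default_rng(20120710)
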