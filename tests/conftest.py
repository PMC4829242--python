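import numpy as np
import pytest

from conjscreen.synthetic import ColourModel, SceneParams, render_scene


@pytest.fixture(scope="session")
def model():
    return ColourModel()


@pytest.fixture(scope="session")
def clean_scene(model):
    """Noise-free daylight scene for a mildly anaemic participant."""
    params = SceneParams(haemoglobin=105.0, lighting_gains=(1, 1, 1), noise_sd=0.0, seed=7)
    return render_scene(params, model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
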