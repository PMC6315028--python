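import numpy as np
import pytest

from scenerecall import pipeline, synth


@pytest.fixture(scope="session")
def small_scene():
    return synth.generate_scene(6, seed=11, image_id="fixture-scene",
                                category="kitchen", n_space_defining=1)


@pytest.fixture(scope="session")
def small_study():
    """A compact end-to-end run shared by integration-style tests."""
    return pipeline.run_synthetic_study(
        seed=5, n_categories=6, n_participants=10, with_attention=False)


@pytest.fixture
def rng():
    return np.random.default_rng(202)
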