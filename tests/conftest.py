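import numpy as np
import pytest

from vesselnet import PipelineParams, make_test_suite, process_image

SUITE_SEED = 0


@pytest.fixture(scope="session")
def suite():
    """The fixed seven-phantom battery, noise-free, seed 0."""
    return make_test_suite(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def default_params():
    return PipelineParams()


@pytest.fixture(scope="session")
def processed_suite(suite, default_params):
    """Full pipeline results for every suite phantom, keyed by phantom name."""
    return {
        spec.name: (image, truth, process_image(image, default_params))
        for image, truth, spec in suite
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
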