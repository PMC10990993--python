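import numpy as np
import pytest

from vtshape import default_validation_suite, generate_phantom


@pytest.fixture(scope="session")
def suite_truths():
    """The five-phantom validation battery, generated once per session."""
    return {spec.run_id: generate_phantom(spec) for spec in default_validation_suite(1)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
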