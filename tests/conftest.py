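import numpy as np
import pytest

from cyclereg import PhantomParams, make_paired_case


@pytest.fixture(scope="session")
def small_params():
    """A quick 96-pixel phantom configuration used by many tests."""
    return PhantomParams(image_size=96, max_disp=4.0, field_smoothness=12.0,
                         seed=42)


@pytest.fixture(scope="session")
def small_case(small_params):
    return make_paired_case(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
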