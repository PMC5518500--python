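import numpy as np
import pytest

from medisr.fixtures import FixtureSpec, generate
from medisr.templates import build_template_bank


@pytest.fixture(scope="session")
def bank():
    return build_template_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def textured_image():
    """A 96x96 band-limited texture with plenty of SIFT structure."""
    return generate(FixtureSpec(kind="smooth_noise", height=96, width=96, seed=11))


@pytest.fixture(scope="session")
def large_texture():
    """A 128x128 texture whose crops serve as matching candidates."""
    return generate(FixtureSpec(kind="smooth_noise", height=128, width=128, seed=7))
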