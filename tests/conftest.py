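import pytest

from hepsim import RngStream, default_config


@pytest.fixture(scope="session")
def doc():
    """The shipped validating-experiment configuration."""
    return default_config()


@pytest.fixture()
def rng():
    return RngStream(12345)
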