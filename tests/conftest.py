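import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile(
    "slideforce", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("slideforce")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
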