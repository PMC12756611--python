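import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
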