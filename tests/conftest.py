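import numpy as np
import pytest
from hypothesis import settings

import thrombochar as tc

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_pair():
    """A small mixed-perviousness phantom pair with ground truth."""
    cfg = tc.ImagingSimConfig(
        shape=(24, 24, 24), spacing=(0.5, 0.5, 0.5), semi_axes_mm=(4.0, 3.0, 3.0),
        pervious_fraction=0.4, uplift_hu=20.0, uplift_noise_sd=4.0, seed=7,
    )
    return tc.simulate_thrombus_pair(cfg)


@pytest.fixture(scope="session")
def registry_cohort():
    """A registry-flavoured cohort with the default injected effects."""
    cfg = tc.registry_like_config(
        n=800, seed=42,
        odds_ratios={"mrs": {"tai_q2_hu": 1.10}, "fps": {"ncct_sd_hu": 0.55}, "etici": {}},
    )
    return tc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
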