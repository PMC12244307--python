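import numpy as np
import pytest

from fishgrowth import GrowthParams

# Published point estimates used as generating truths in recovery studies:
# age-at-length world (Bayesian fit), increment world (Fabens fits), and
# the length-frequency world (ELEFAN fit).
VBGM_BAYES_TRUTH = GrowthParams(524.46, 0.21, t0=0.0, sigma=35.0)
FABENS_FREQ_TRUTH = GrowthParams(538.85, 0.37, sigma=15.0)
FABENS_BAYES_TRUTH = GrowthParams(536.82, 0.38, sigma=15.0)
ELEFAN_TRUTH = GrowthParams(436.50, 0.12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240401)
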