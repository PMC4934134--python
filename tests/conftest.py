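import numpy as np
import pytest
from hypothesis import settings

from subrandom import EntropyConfig

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

#: Fitted digram weights reported for the asymmetric-entropy model, in the
#: canonical category order (XX, OO, XO, OX).
FITTED_WEIGHTS = (0.30, 0.33, 0.68, 0.69)

PA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@pytest.fixture
def marcellin_config() -> EntropyConfig:
    return EntropyConfig(family="marcellin", weights=FITTED_WEIGHTS)


@pytest.fixture
def shannon_config() -> EntropyConfig:
    return EntropyConfig(family="shannon")
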