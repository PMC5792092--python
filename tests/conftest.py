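import dataclasses

import numpy as np
import pytest

from erstress.synthetic import default_truth


@pytest.fixture
def truth():
    return default_truth(seed=1234)


@pytest.fixture
def noiseless_truth(truth):
    return dataclasses.replace(
        truth, noise_cv={"blot": 0.0, "intensity": 0.0, "em": 0.0}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
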