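import numpy as np
import pytest

from mycomorph import (
    LogisticParams,
    LuedekingPiretParams,
    anchored_reference_params,
)
from mycomorph.reference import MORPHOLOGIES


@pytest.fixture(params=MORPHOLOGIES)
def morphology(request):
    return request.param


@pytest.fixture
def anchored(morphology):
    """Anchored reference trajectory for one morphology."""
    return anchored_reference_params(morphology)


@pytest.fixture
def fluffy_params():
    p, lp = anchored_reference_params("fluffy_pellet")
    return p, lp


@pytest.fixture
def random_param_sets():
    """Seeded sweep of valid logistic + Luedeking-Piret parameter sets."""
    rng = np.random.default_rng(42)
    sets = []
    for _ in range(20):
        x_m = rng.uniform(5.0, 40.0)
        p = LogisticParams(
            mu_max=rng.uniform(0.2, 2.0),
            x_m=x_m,
            x_0=rng.uniform(0.02, 0.9) * x_m,
        )
        lp = LuedekingPiretParams(
            alpha=rng.uniform(0.0, 1.0),
            beta=rng.uniform(0.0, 0.05),
            p_0=rng.uniform(0.0, 1.0),
        )
        sets.append((p, lp))
    return sets
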