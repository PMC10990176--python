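import numpy as np
import pytest

from riclpm import (
    CohortConfig,
    RiclpmOptions,
    build_ri_ar,
    build_riclpm,
    default_truth,
)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def riclpm_model():
    return build_riclpm(RiclpmOptions())


@pytest.fixture(scope="session")
def ri_ar_model():
    return build_ri_ar(RiclpmOptions())


@pytest.fixture(scope="session")
def desk_config():
    """Small, fast cohort: 14-day wear period, published flow counts."""
    return CohortConfig.desk(seed=11)


def simulate_from_moments(mu, sigma, n, seed):
    """Independent draw used as a cross-check against implied moments."""
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.asarray(mu), np.asarray(sigma), size=n)
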