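import numpy as np
import pytest

from dietrisk import DistributionSpec, EvmmSpec, MixtureSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lognormal_gpd_spec():
    """A known spliced-tail truth used across modules."""
    bulk = DistributionSpec.lognormal(-1.5, 0.9)
    u = float(bulk.quantile(0.88))
    return EvmmSpec(bulk=bulk, threshold=u, tail_shape=0.4, tail_scale=0.3)


@pytest.fixture
def two_gamma_spec():
    """A well-separated two-component gamma truth."""
    return MixtureSpec(
        weights=(0.4, 0.6),
        components=(DistributionSpec.gamma(2, 8), DistributionSpec.gamma(30, 20)),
    )
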