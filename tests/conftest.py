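import numpy as np
import pytest
from scipy import stats

from cutroc import BiomarkerSample, DistributionEstimate


def dist_from_scipy(d) -> DistributionEstimate:
    """Wrap a frozen scipy distribution in the package's CDF contract."""
    return DistributionEstimate(
        cdf=d.cdf,
        quantile=d.ppf,
        support_hint=(float(d.ppf(0.001)), float(d.ppf(0.999))),
    )


@pytest.fixture
def normal_pair():
    """Equal-variance binormal truth N(0,1) vs N(1,1)."""
    return dist_from_scipy(stats.norm(0, 1)), dist_from_scipy(stats.norm(1, 1))


@pytest.fixture
def binormal_sample():
    rng = np.random.default_rng(42)
    return BiomarkerSample(rng.normal(0, 1, 100), rng.normal(1, 1, 100))


@pytest.fixture
def large_binormal_sample():
    rng = np.random.default_rng(7)
    return BiomarkerSample(rng.normal(0, 1, 5000), rng.normal(1, 1, 5000))
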