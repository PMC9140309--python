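import pytest

from egug.baselines import make_baseline
from egug.egunh import EGuNHParams, to_family_params


@pytest.fixture(scope="session")
def nh_params():
    """Reference EGuNH parameter set used in the printed quantile table."""
    return EGuNHParams(theta=2.1, sigma=0.29, alpha=1.5)


@pytest.fixture(scope="session")
def nh_family(nh_params):
    return to_family_params(nh_params)


@pytest.fixture(scope="session")
def shape_grid():
    """Family shape pairs spanning small/unit/large theta and sigma."""
    return [(t, s) for t in (0.3, 1.0, 3.0) for s in (0.3, 1.0, 3.0)]


@pytest.fixture(scope="session")
def baseline_examples():
    """One representative of each registered baseline."""
    return [
        make_baseline("exponential", alpha=1.3),
        make_baseline("weibull", a=0.8, b=1.7),
        make_baseline("rayleigh", a=0.5),
        make_baseline("burr12", a=2.0, b=1.5),
        make_baseline("nh", alpha=1.4, lam=0.9),
    ]


@pytest.fixture(scope="session")
def synthetic_sample():
    """A fixed EGuNH sample used by the estimation tests."""
    from egug.egunh import egunh_sample

    truth = EGuNHParams(theta=2.2, sigma=0.45, alpha=0.5)
    return truth, egunh_sample(500, truth, seed=1)
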