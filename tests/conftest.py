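import numpy as np
import pytest

from gompcens import GompertzPHParams, CovariateVector, DoubleCensoredDataset


@pytest.fixture
def ref_params():
    """Moderate Gompertz parameters with nonzero covariate effects."""
    return GompertzPHParams(np.log(0.02), 0.1, (-0.5, -0.3, -0.1, 0.2, 0.4), -0.2)


@pytest.fixture
def exp_params():
    """Exponential submodel (constant hazard 0.5/yr, no covariates)."""
    return GompertzPHParams(np.log(0.5), 0.0)


@pytest.fixture
def z_ref():
    return CovariateVector()


def make_exponential_dataset(rate, n, r_cens, seed):
    """Right-censored exponential durations, no covariates."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, n)
    y = np.minimum(t, r_cens)
    delta = np.where(t <= r_cens, 0, 1)
    return DoubleCensoredDataset(y, delta)


def make_double_censored_exponential(rate, n, l, r, seed):
    """Doubly censored exponential durations with fixed entry/exit ages."""
    from gompcens import classify_observation

    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, n)
    y, delta = classify_observation(t, np.full(n, l), np.full(n, r))
    return DoubleCensoredDataset(y, delta)
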