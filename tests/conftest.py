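import numpy as np
import pytest

from sirforce import FullParams, ReducedParams, hopf_thresholds

#: reference parameter triple used throughout the analysis
LAM, ALPHA, DELTA = 0.9, 0.1, 1.1


@pytest.fixture(scope="session")
def base_params() -> ReducedParams:
    """Reference triple with a placeholder beta (swap in via with_beta)."""
    return ReducedParams(lam=LAM, beta=1.0, alpha=ALPHA, delta=DELTA)


@pytest.fixture(scope="session")
def thresholds(base_params):
    th = hopf_thresholds(base_params)
    assert th.exists
    return th


@pytest.fixture(scope="session")
def beta_mid(thresholds) -> float:
    return (thresholds.beta1 + thresholds.beta2) / 2.0


@pytest.fixture(scope="session")
def mid_params(base_params, beta_mid) -> ReducedParams:
    return base_params.with_beta(beta_mid)


@pytest.fixture(scope="session")
def full_params(beta_mid) -> FullParams:
    """Full-system parameters consistent with the reference reduced triple:
    alpha = a_raw + mu = 0.1, delta = g + mu = 1.1."""
    return FullParams(lam=LAM, beta=beta_mid, a_raw=0.05, g=1.05, mu=0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
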