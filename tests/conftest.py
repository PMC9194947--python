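import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_factor_data():
    """A small, fast draw from the factor model (p=200) with its
    train/validation/test splits."""
    from suffpcr.simulate import FactorModelParams, generate_splits

    params = FactorModelParams(n=100, p=200, d=3, r=5, seed=7)
    return generate_splits(params)


def random_correlation(rng, p: int) -> np.ndarray:
    """Sample correlation matrix of a random Gaussian sample (n > p so
    it is well conditioned)."""
    X = rng.standard_normal((3 * p, p)) @ rng.standard_normal((p, p))
    X = X - X.mean(axis=0)
    X = X / X.std(axis=0)
    return X.T @ X / X.shape[0]
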