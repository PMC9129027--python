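import numpy as np
import pytest

from medbayes.core import EffectPriorSpec, MediationData, standardize_trait


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def default_priors():
    return EffectPriorSpec()


def random_dataset(rng, n=20, d=2, binary_x=True, covariates=0):
    """Standardized random dataset with no built-in causal structure."""
    X = (rng.integers(0, 2, (n, d)).astype(float) if binary_x
         else rng.standard_normal((n, d)))
    y = standardize_trait(rng.standard_normal(n))
    m = standardize_trait(rng.standard_normal(n))
    Z = rng.standard_normal((n, covariates)) if covariates else None
    return MediationData(y=y, m=m, X=X, Z_m=Z, Z_y=Z)


@pytest.fixture
def small_data(rng):
    return random_dataset(rng, n=12, d=1)
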