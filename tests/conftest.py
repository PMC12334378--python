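import numpy as np
import pytest

from modinvar import ParameterVector, fit_ml, mediation_spec
from modinvar.sem_core import ModelSpec, implied_moments


@pytest.fixture(scope="session")
def spec():
    return mediation_spec()


@pytest.fixture(scope="session")
def true_theta(spec):
    rng = np.random.default_rng(12)
    return ParameterVector(
        alpha=rng.normal(3.0, 0.5, 9),
        lam=rng.uniform(0.7, 1.3, 6),
        theta=rng.uniform(0.4, 0.9, 9),
        psi=np.array([0.6, 0.4, 0.3]),
        beta=np.array([0.3, 0.1, -0.2]),
    )


@pytest.fixture(scope="session")
def med_data(spec, true_theta):
    """Homogeneous mediation data plus an independent standardized moderator."""
    rng = np.random.default_rng(7)
    mu, sigma = implied_moments(true_theta, spec)
    y = rng.multivariate_normal(mu, sigma, size=400)
    z = rng.standard_normal(400)
    z = (z - z.mean()) / z.std()
    return y, z


@pytest.fixture(scope="session")
def med_fit(spec, med_data):
    y, _ = med_data
    return fit_ml(y, spec)


@pytest.fixture(scope="session")
def onefac_spec():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ModelSpec(factors=("F",), indicators={"F": ("a", "b", "c")})
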