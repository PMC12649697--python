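import numpy as np
import pytest

from psynetkit import default_scenario
from psynetkit.estimation import EstimationSettings


def mvn_from_precision(K: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Standardized multivariate-normal draws with correlation inv(K) scaled."""
    C = np.linalg.inv(K)
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    return rng.standard_normal((n, K.shape[0])) @ np.linalg.cholesky(C).T


@pytest.fixture(scope="session")
def fast_settings() -> EstimationSettings:
    """Coarser penalty path for resampling-heavy tests."""
    return EstimationSettings(
        n_lambda=20, lambda_min_ratio=0.1, convergence_tol=1e-4, max_iter=200
    )


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(n_per_group=766, seed=7)
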