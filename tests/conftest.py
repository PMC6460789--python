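import numpy as np
import pytest

from surromix import em_fit


@pytest.fixture(scope="session")
def planted_crossing():
    """Two regressions crossing at the origin: slopes +2/−2, sigma 0.5, n=2000.

    Membership is undecidable near z=0, so posterior sharpness is bounded by
    the true-model posterior, which the tests compute as an oracle.
    """
    rng = np.random.default_rng(42)
    n = 2000
    z = rng.standard_normal((n, 1))
    labels = rng.random(n) < 0.5
    y = np.where(labels, 2.0, -2.0) * z[:, 0] + rng.normal(0.0, 0.5, n)
    return z, y, labels


@pytest.fixture(scope="session")
def planted_separated():
    """Well-separated pair: intercepts ±3 and slopes ±2, sigma 0.5, n=2000.

    The 6-unit mean offset keeps the components ~12 residual SDs apart
    everywhere, so posteriors are near-degenerate for essentially all
    subjects.
    """
    rng = np.random.default_rng(42)
    n = 2000
    z = rng.standard_normal((n, 1))
    labels = rng.random(n) < 0.5
    y = (
        np.where(labels, 3.0, -3.0)
        + np.where(labels, 2.0, -2.0) * z[:, 0]
        + rng.normal(0.0, 0.5, n)
    )
    return z, y, labels


@pytest.fixture(scope="session")
def separated_fit(planted_separated):
    z, y, _ = planted_separated
    return em_fit(z, y, K=2, n_starts=10, seed=3)


@pytest.fixture(scope="session")
def crossing_fit(planted_crossing):
    z, y, _ = planted_crossing
    return em_fit(z, y, K=2, n_starts=10, seed=3)
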