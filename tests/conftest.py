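import numpy as np
import pytest

from avitrend import CountMatrix


@pytest.fixture
def complete_2x2():
    """The textbook complete matrix whose indices are (1, 2) exactly."""
    return CountMatrix(
        counts=np.array([[10.0, 20.0], [30.0, 60.0]]),
        mask=np.ones((2, 2), bool),
        years=np.array([2000, 2001]),
    )


@pytest.fixture
def three_cell():
    """Three observed cells, one missing: the fit is exact (3 parameters)."""
    return CountMatrix(
        counts=np.array([[10.0, 20.0], [30.0, 0.0]]),
        mask=np.array([[True, True], [True, False]]),
        years=np.array([2000, 2001]),
    )


def random_count_matrix(rng, n_sites, n_years, missing_rate=0.0, trend=1.02):
    """Small random Poisson instance guaranteed to be fittable."""
    while True:
        a = rng.lognormal(2.5, 0.5, n_sites)
        g = trend ** np.arange(n_years) * rng.lognormal(0, 0.1, n_years)
        g = g / g[0]
        f = rng.poisson(np.outer(a, g)).astype(float)
        mask = rng.random((n_sites, n_years)) >= missing_rate
        # keep every site and year observed at least once so the fit is defined
        if mask.all(axis=1).any() and mask.any(axis=0).all() and mask.any(axis=1).all():
            return CountMatrix(
                counts=f, mask=mask, years=np.arange(2000, 2000 + n_years)
            )
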