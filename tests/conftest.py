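import numpy as np
import pytest

from inue import NRateTrial, PriceSet, QPFit

RATES6 = np.array([0.0, 45.0, 90.0, 135.0, 180.0, 225.0])


def qp_yield(a, b, c, n):
    """Reference quadratic-plateau evaluation (independent of the package)."""
    n = np.asarray(n, dtype=float)
    x0 = -b / (2 * a)
    return np.where(n <= x0, c + b * n + a * n * n, c + b * x0 + a * x0 * x0)


def make_trial(a=-0.15, b=45.0, c=5000.0, rates=RATES6, noise_sd=0.0, seed=0, reps=1):
    rng = np.random.default_rng(seed)
    rr = np.tile(rates, reps)
    y = qp_yield(a, b, c, rr) + (rng.normal(0, noise_sd, rr.size) if noise_sd else 0.0)
    return NRateTrial("T001", 2001, rr, np.maximum(y, 0.0))


def make_fit(a=-0.15, b=45.0, c=5000.0, site="T001", year=2001, dataset="") -> QPFit:
    """QPFit assembled directly from known coefficients (bypasses fitting)."""
    x0 = -b / (2 * a)
    return QPFit(
        site_id=site,
        year=year,
        a=a,
        b=b,
        c=c,
        x0=x0,
        plateau_yield=c - b * b / (4 * a),
        r2=1.0,
        f_pvalue=0.0,
        sse=0.0,
        sst=1.0,
        n_obs=6,
        max_rate_applied=225.0,
        dataset=dataset,
    )


@pytest.fixture
def example_fit():
    return make_fit()


@pytest.fixture
def prices():
    return PriceSet()
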