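import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from casecross.simulate import DEFAULT_CONFIG, simulate_study

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

# small but complete study used by several integration tests
SMALL_CONFIG = dataclasses.replace(
    DEFAULT_CONFIG,
    n_block_groups=60,
    n_tracts=15,
    grid_nx=8,
    grid_ny=8,
    start="2001-01-01",
    end="2001-12-31",
)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SMALL_CONFIG, seed=7)


@pytest.fixture(scope="session")
def small_design(small_study):
    from casecross.pipeline import prepare_design

    design, log = prepare_design(
        small_study.events, small_study.exposure, census=small_study.census
    )
    return design


def random_matched_sets(rng, n_sets, beta, n_referents=(4, 10), x_sd=1.0):
    """One-covariate matched sets drawn from the conditional-logistic model.

    The case row of each set is chosen with softmax(beta * x) probability, so
    ``beta`` is the true generating coefficient. Returns (y, x, groups).
    """
    ys, xs, gs = [], [], []
    for g in range(n_sets):
        m = rng.integers(*n_referents)
        x = rng.normal(0.0, x_sd, m + 1)
        p = np.exp(beta * x - (beta * x).max())
        p /= p.sum()
        case = rng.choice(m + 1, p=p)
        y = np.zeros(m + 1)
        y[case] = 1.0
        ys.append(y)
        xs.append(x)
        gs.append(np.full(m + 1, g))
    return np.concatenate(ys), np.concatenate(xs), np.concatenate(gs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
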