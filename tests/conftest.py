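import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

import phagedorm as pg

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig2():
    return pg.scenario("fig2_darkgreen")


@pytest.fixture(scope="session")
def fig3():
    return pg.scenario("fig3_blue")


@pytest.fixture(scope="session")
def fig4():
    return pg.scenario("fig4_purple")


@pytest.fixture(scope="session")
def fig5():
    return pg.scenario("fig5_lightgreen")


@pytest.fixture(scope="session")
def fig6():
    return pg.scenario("fig6_red")


@st.composite
def model_params(draw, require_cost=False):
    """Random valid parameter sets; with ``require_cost`` the dormancy
    trait carries a reproductive cost (lambda2 < lambda1)."""
    mu1 = draw(st.floats(0.2, 1.2))
    lam1 = draw(st.floats(mu1 + 0.5, mu1 + 3.0))
    hi = lam1 if require_cost else lam1 + 1.0
    lam2 = draw(st.floats(mu1 + 0.05, hi, exclude_max=True))
    p = pg.ModelParams(
        lambda1=lam1, lambda2=lam2, mu1=mu1,
        C=draw(st.floats(0.5, 2.0)),
        D=draw(st.floats(0.2, 1.0)),
        q=draw(st.floats(0.05, 0.95)),
        r=draw(st.floats(0.2, 2.0)),
        v=draw(st.floats(0.2, 2.0)),
        m=draw(st.integers(3, 20)),
        sigma=draw(st.floats(0.5, 3.0)),
        kappa=draw(st.floats(0.0, 1.0)),
        mu3=draw(st.floats(0.2, 1.5)),
    )
    # keep away from the degenerate virion-balance surface
    if abs(p.r * p.kappa * p.mu1 - p.v * p.sigma) < 1e-6:
        p = p.replace(sigma=p.sigma + 0.1)
    return p


def random_params(rng, require_cost=True):
    """numpy-seeded analogue of the hypothesis strategy, for bulk sweeps."""
    mu1 = rng.uniform(0.2, 1.2)
    lam1 = mu1 + rng.uniform(0.5, 3.0)
    lam2 = mu1 + rng.uniform(0.05, 1.0) * ((lam1 - mu1) if require_cost
                                           else (lam1 - mu1 + 1.0))
    p = pg.ModelParams(
        lambda1=lam1, lambda2=min(lam2, lam1 - 1e-6) if require_cost else lam2,
        mu1=mu1, C=rng.uniform(0.5, 2.0), D=rng.uniform(0.2, 1.0),
        q=rng.uniform(0.05, 0.95), r=rng.uniform(0.2, 2.0),
        v=rng.uniform(0.2, 2.0), m=int(rng.integers(3, 21)),
        sigma=rng.uniform(0.5, 3.0), kappa=rng.uniform(0.0, 1.0),
        mu3=rng.uniform(0.2, 1.5))
    if abs(p.r * p.kappa * p.mu1 - p.v * p.sigma) < 1e-6:
        p = p.replace(sigma=p.sigma + 0.1)
    return p
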