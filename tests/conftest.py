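import numpy as np
import pytest

import multievent as me
from multievent.params import CovariateSeries, ParameterSet


@pytest.fixture(scope="session")
def space():
    return me.build_state_space(4, 3, 2)


@pytest.fixture(scope="session")
def covariates3():
    rng = np.random.default_rng(7)
    return CovariateSeries(np.arange(2000, 2003), rng.standard_normal(3),
                           rng.standard_normal(3))


def random_params(rng, n_areas=4):
    """A valid random ParameterSet draw for property tests."""
    return ParameterSet.from_probs(
        phi=rng.uniform(0.2, 0.98, n_areas),
        c=rng.uniform(0.0, 0.32),
        delta=rng.uniform(0.0, 0.4),
        p_aware=rng.uniform(0.05, 0.95),
        p_unaware=rng.uniform(0.05, 0.95),
        pi=rng.dirichlet(np.ones(n_areas)),
        rho=rng.uniform(0.3, 1.0),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A reproducible small simulated study used across tests."""
    cfg = me.default_paper_config(n_individuals=300, seed=42)
    return me.simulate_dataset(cfg)
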