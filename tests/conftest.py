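import numpy as np
import pytest

from avwgmm import TrainingConfig, avozes_defaults, train_replications
from avwgmm.mixture import Mixture


@pytest.fixture(scope="session")
def bd():
    return avozes_defaults("bd")


@pytest.fixture(scope="session")
def bg():
    return avozes_defaults("bg")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mixture(rng, K=5, label="x"):
    phi = rng.random(K) + 0.05
    phi /= phi.sum()
    return Mixture(mu=rng.normal(0, 5, K), sigma=rng.uniform(0.5, 3, K),
                   phi=phi, label=label)


@pytest.fixture(scope="session")
def small_config():
    """A short training configuration for fast end-to-end checks."""
    return TrainingConfig(n_trials=2000, checkpoints=(100, 2000), n_reps=3,
                          base_seed=99)


@pytest.fixture(scope="session")
def small_result(bd, small_config):
    """Three short replications of the /b/-/d/ simulation."""
    return train_replications(bd, small_config)


@pytest.fixture(scope="session")
def trained_model(bd):
    """One replication trained long enough to categorize reliably."""
    cfg = TrainingConfig(n_trials=30_000, checkpoints=(30_000,), n_reps=1,
                         base_seed=7)
    return train_replications(bd, cfg).model(30_000, 0)
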