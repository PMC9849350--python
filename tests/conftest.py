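"""Shared fixtures: small synthetic datasets and a trained model.

Session-scoped so the expensive pieces (simulation, training) are built once
and reused by every test that only needs to *read* them.
"""

import numpy as np
import pytest

from capsite.model import BindingSiteModel, bundles_from_dataset
from capsite.network import ModelConfig
from capsite.synth import SimConfig, simulate_dataset

#: A deliberately small network: big enough to learn the planted signal,
#: small enough that a full fit takes seconds.
TINY_MODEL = dict(
    hidden_sizes=(8,),
    caps_in_dim=4,
    caps_count=8,
    caps_dim=4,
    routing_iters=2,
    epochs=10,
    patience=4,
)

TINY_SIM = dict(n_proteins=8, length_range=(30, 45), embedding_dim=48)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(SimConfig(seed=5, **TINY_SIM))


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(seed=5, **TINY_MODEL)


@pytest.fixture(scope="session")
def tiny_bundles(tiny_dataset, tiny_config):
    return bundles_from_dataset(tiny_dataset, tiny_config)


@pytest.fixture(scope="session")
def fitted_results(tiny_dataset, tiny_config):
    """A small undersampled single-model fit shared by read-only tests."""
    model = BindingSiteModel.from_dataset(
        tiny_dataset, tiny_config, strategy="undersample"
    )
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
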