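import numpy as np
import pytest

from fedfilter import ClientState, ModelSpec, SyntheticSpec, split_dataset
from fedfilter.synthetic import generate_base_population


@pytest.fixture(scope="session")
def tiny_spec():
    """A small, fast population: 2 clients, few hundred samples."""
    return SyntheticSpec(n_clients=2, samples_per_client=(240, 120),
                         n_features=10, n_informative=6, latent_dim=4,
                         class_prevalence=0.3, seed=7)


@pytest.fixture()
def tiny_clients(tiny_spec):
    """Two split ClientStates on the tiny population (function-scoped: tests
    mutate filter state)."""
    pop = generate_base_population(tiny_spec)
    out = []
    for i, ds in enumerate(pop):
        ds = split_dataset(ds, seed=100 + i)
        out.append(ClientState(client_id=ds.client_id, data=ds,
                               batch_size=32, filter_depth=2))
    return out


@pytest.fixture(scope="session")
def ff_spec():
    return ModelSpec(kind="feedforward", input_dim=8, hidden_dim=16, output_dim=1)


def rng(seed=0):
    return np.random.default_rng(seed)
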