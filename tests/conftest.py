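import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from vrank_cascade import (  # noqa: E402
    ConvergenceParams,
    NetworkParams,
    ScenarioConfig,
    ShockParams,
    generate_network,
)
from vrank_cascade.fixtures import _net_from_coords  # noqa: E402


@pytest.fixture(scope="session")
def small_net():
    """A 20-node connected spatial network, deterministic."""
    return generate_network(n_nodes=20, food_frac=0.5, target_mean_degree=4, seed=7)


@pytest.fixture(scope="session")
def experiment_net():
    """An 80-node network with the default experiment geometry."""
    return generate_network(n_nodes=80, food_frac=0.5, target_mean_degree=8, seed=0)


def make_pair_net(both_food: bool = False):
    """Two connected nodes; mixed producer types by default."""
    coords = np.array([[0.3, 0.5], [0.7, 0.5]])
    is_food = np.array([True, True]) if both_food else np.array([True, False])
    return _net_from_coords(coords, is_food, [(0, 1)])


@pytest.fixture()
def small_cfg():
    """A fast scenario for 20-node runs."""
    return ScenarioConfig(
        network=NetworkParams(n_nodes=20, target_mean_degree=4),
        shock=ShockParams(magnitude=0.6, t_shock=800),
        convergence=ConvergenceParams(t_max=2000),
        seed=7,
    ).validate()
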