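import numpy as np
import pandas as pd
import pytest

from heatlogic import logictree as lt
from heatlogic import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_weather():
    """Six synthetic years of hourly weather (fast enough for unit tests)."""
    return syn.simulate_hourly_weather(syn.WeatherGenConfig(n_years=6, seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """One six-year E1 realisation at RR 1.05 with the high-count profile."""
    return syn.simulate_dataset(
        syn.ScenarioSpec("E1", true_rr=1.05),
        weather_config=syn.WeatherGenConfig(n_years=6, seed=7),
        seed=5,
    )


def random_tree(rng, k: int, max_leaves: int) -> lt.LogicTree:
    """Random full-binary logic tree with 1..max_leaves leaves."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    nodes = [lt.Leaf(int(rng.integers(k)), bool(rng.integers(2))) for _ in range(n_leaves)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        op = "and" if rng.integers(2) else "or"
        merged = lt.Node(op, nodes[i], nodes[j])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return lt.LogicTree(nodes[0])
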