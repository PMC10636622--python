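import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sewersense as ss

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_panel():
    """One study-emulating synthetic panel (7 west + 5 east, 11 analytes)."""
    cfg = ss.default_config(seed=42)
    plants, measurements, truth = ss.generate_panel(cfg)
    return plants, measurements, truth


@pytest.fixture(scope="session")
def default_loads(default_panel):
    plants, measurements, _ = default_panel
    return ss.compute_loads(plants, measurements)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_labeled_panel(rng, n_west=6, n_east=6, n_vars=3, effect=0.0):
    """Small random feature matrix + region labels for discriminant tests."""
    n = n_west + n_east
    x = pd.DataFrame(
        rng.normal(size=(n, n_vars)),
        columns=[f"v{i}" for i in range(n_vars)],
        index=[f"p{i:02d}" for i in range(n)],
    )
    x.iloc[:n_west, 0] += effect
    labels = ["west"] * n_west + ["east"] * n_east
    return x, labels
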