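import numpy as np
import pandas as pd
import pytest

from planktonet import simulate
from planktonet.data_model import AsvTable


@pytest.fixture(scope="session")
def small_dataset():
    """Default synthetic three-year survey (60 samples, ~150 ASVs)."""
    return simulate.generate_community(seed=42)


@pytest.fixture(scope="session")
def module_dataset():
    """All-persistent community whose phytoplankton ASVs form 4 planted modules."""
    return simulate.generate_community(
        n_stations=10,
        ephemeral_fraction=0.0,
        include_known_pair=False,
        module_spec={"n_modules": 4, "module_size": None, "loading": 3.0},
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def tiny_table():
    data = pd.DataFrame(
        [[10, 0, 5], [3, 7, 2], [1, 1, 8]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3"],
    )
    return AsvTable(data, marker="16S")
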