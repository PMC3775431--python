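import numpy as np
import pandas as pd
import pytest

from plasmodebench.data_model import CountMatrix, DesignTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_design():
    def make(n_per_group, prefix="s", block=None):
        n = 2 * n_per_group
        df = pd.DataFrame(
            {
                "sample_id": [f"{prefix}{i+1}" for i in range(n)],
                "treatment": ["g1"] * n_per_group + ["g2"] * n_per_group,
            }
        )
        if block is not None:
            df["block"] = block
        return DesignTable(df)

    return make


@pytest.fixture
def small_dataset(two_group_design):
    """4 genes x 6 samples with one clearly DE gene."""
    counts = np.array(
        [
            [10, 12, 9, 50, 55, 60],
            [20, 18, 22, 21, 19, 20],
            [5, 7, 6, 6, 5, 7],
            [100, 90, 110, 95, 105, 100],
        ]
    )
    cm = CountMatrix(["gA", "gB", "gC", "gD"], [f"s{i+1}" for i in range(6)], counts)
    return cm, two_group_design(3)
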