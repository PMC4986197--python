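import numpy as np
import pandas as pd
import pytest

from drivermod.data_io import GroupLabels
from drivermod.synthetic import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def shared_driver_dataset():
    """Default study conditions: 5 modules x 20 genes, 60+60 samples, shared drivers."""
    return generate_bundle(SimConfig(seed=42))


@pytest.fixture(scope="session")
def comparative_dataset():
    """Group-specific drivers for comparative tests (small, fast)."""
    # 40 samples per group keeps the minority leaf of an 85%-aberrant CNV
    # driver above min_leaf in single-condition runs
    cfg = SimConfig(
        seed=7,
        n_samples=(40, 40),
        n_modules=3,
        module_size=10,
        n_passengers=12,
        n_shared_modulators=1,
        n_group_a_modulators=1,
        n_group_b_modulators=1,
    )
    return generate_bundle(cfg)


@pytest.fixture()
def two_group_labels():
    samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    return GroupLabels(pd.Series(["x"] * 6 + ["y"] * 6, index=samples))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
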