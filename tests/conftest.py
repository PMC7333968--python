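import numpy as np
import pandas as pd
import pytest

from trophfa import AssayConfig, FAProfileTable, generate_assay


@pytest.fixture
def simple_table() -> FAProfileTable:
    """Three samples x three FA, already closed."""
    values = pd.DataFrame(
        {
            "16:0": [50.0, 60.0, 40.0],
            "18:1w9": [30.0, 20.0, 35.0],
            "20:5w3": [20.0, 20.0, 25.0],
        },
        index=["s1", "s2", "s3"],
    )
    meta = pd.DataFrame(
        {"role": ["consumer"] * 3, "treatment": ["a", "a", "b"]},
        index=values.index,
    )
    return FAProfileTable(values, meta)


@pytest.fixture(scope="session")
def default_assay():
    """One seeded assay at the default study conditions (5 x (5, 5))."""
    cfg = AssayConfig()
    foods, consumers, truth = generate_assay(cfg, seed=7)
    pairing = {name: name for name, _, _ in cfg.treatments}
    return cfg, foods, consumers, truth, pairing


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
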