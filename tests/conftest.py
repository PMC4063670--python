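import numpy as np
import pandas as pd
import pytest

from translatome import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimConfig(n_genes=300, seed=11, n_active_up=8, n_active_down=8)


@pytest.fixture(scope="session")
def small_polysome(small_config):
    return synthetic.gen_polysome_dataset(small_config)


@pytest.fixture
def toy_signal_table():
    """One gene, one replicate, both conditions, hand-set linear signals."""
    rows = []
    for condition in ("control", "stimulated"):
        for pool, signal in zip("FSLH", (10.0, 10.0, 40.0, 40.0)):
            rows.append(
                {"gene_id": "g1", "condition": condition, "replicate": 1, "pool": pool, "signal": signal}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def unit_fractions():
    return pd.DataFrame(
        [
            {"pool": p, "condition": c, "fraction": 1.0}
            for p in "FSLH"
            for c in ("control", "stimulated")
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
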