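import numpy as np
import pandas as pd
import pytest

import pica


@pytest.fixture(scope="session")
def sim_default():
    """Default-scale simulated dataset (1000 eQTLs, 500 samples, 3 contexts)."""
    return pica.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def sim_small():
    """Small, strong-signal dataset for fast pipeline tests."""
    cfg = pica.SimulationConfig(n_samples=300, n_eqtls=300, n_contexts=2,
                                fraction_interacting=0.3, seed=42)
    return pica.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_expression():
    values = pd.DataFrame(
        [[1.0, 2.0, 4.0], [8.0, 4.0, 2.0], [3.0, 3.0, 9.0]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"],
    )
    return pica.ExpressionMatrix(values, state="raw")
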