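import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230419)


@pytest.fixture
def small_synthetic_config():
    from adiponet.synthetic import SyntheticConfig

    return SyntheticConfig(
        n_lean=15, n_overweight=15, n_obese=15, n_paired=10, seed=101
    )


@pytest.fixture
def independent_gene_table(rng):
    """8 mutually independent pseudo-genes, n=100."""
    genes = [f"N{i}" for i in range(8)]
    return pd.DataFrame(rng.normal(size=(100, 8)), columns=genes)
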