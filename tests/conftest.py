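import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published_fixtures():
    from stimmod import load_published_modules

    modules, counts = load_published_modules()
    return modules, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(20120)


@pytest.fixture()
def small_gene_table(rng):
    """A 50-gene x 6-sample log2 table with three stim/ctrl pairs."""
    genes = [f"g{i}" for i in range(50)]
    cols = ["stim_1", "ctrl_1", "stim_2", "ctrl_2", "stim_3", "ctrl_3"]
    return pd.DataFrame(
        rng.normal(8, 1, size=(50, 6)), index=pd.Index(genes, name="symbol"), columns=cols
    )
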