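import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import salicore as sc

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel300() -> sc.TraitTable:
    """Default synthetic 300-genotype panel, shared across tests."""
    return sc.simulate_trait_table(sc.SyntheticSpec(n_genotypes=300, seed=20240301))


@pytest.fixture()
def tiny_table() -> sc.TraitTable:
    """3 genotypes x 2 traits with hand-checkable membership values."""
    data = pd.DataFrame(
        {"RGR": [0.2, 0.5, 0.8], "Sen": [4.0, 6.0, 8.0]},
        index=["g1", "g2", "g3"],
    )
    data.index.name = "genotype_id"
    return sc.TraitTable(data, {"RGR": "positive", "Sen": "negative"})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(77)
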