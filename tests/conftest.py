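import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import senomob as sm

settings.register_profile(
    "senomob",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("senomob")


@pytest.fixture(scope="session")
def toy_genome():
    """A small shared reference genome with all feature tracks."""
    spec = sm.ToyGenomeSpec(seed=101, n_chroms=2, chrom_length=30_000, mt_length=5_000)
    return sm.make_toy_genome(spec)


@pytest.fixture(scope="session")
def senescent_sample(toy_genome):
    return sm.plant_de_novo_events(
        toy_genome,
        n_sva=3,
        n_numt=4,
        params=sm.PlantParams(mt_len_range=(50, 130)),
        seed=102,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
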