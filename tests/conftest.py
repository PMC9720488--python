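import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from resgwas.simulate import Pedigree, SimulationConfig, simulate_batch

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_pedigree(rows) -> Pedigree:
    """rows: (animal, sire, dam, sex, hatch_week) tuples, '' = unknown."""
    table = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "hatch_week"])
    table["family"] = -1
    table["row"] = -1
    return Pedigree(table)


@pytest.fixture(scope="session")
def small_batch():
    """A reduced batch shared by read-only tests."""
    cfg = SimulationConfig(
        n_hens=300, n_families=60, n_sires=12, n_genotyped=150, n_snps=300
    )
    return simulate_batch(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
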