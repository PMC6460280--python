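import numpy as np
import pytest

from fostag import simlib
from fostag.core import SeqRecord


@pytest.fixture(scope="session")
def small_pool() -> simlib.SimResult:
    """Error-free 5-clone pool with ~12 kb inserts (fast shared fixture)."""
    cfg = simlib.SimConfig(
        seed=101,
        n_clones=5,
        coverage=30,
        insert_mean=12000,
        insert_sd=1000,
        insert_min=10000,
        insert_max=14000,
    )
    return simlib.simulate_pool(cfg)


@pytest.fixture(scope="session")
def vector_ref(small_pool) -> list[SeqRecord]:
    return [SeqRecord("vector", small_pool.clones[0].vector.backbone)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2019)
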