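import numpy as np
import pytest

from vpseq.read_index import build_store
from vpseq.seqio import Read
from vpseq.simulate import SimConfig, simulate_dataset


def random_read(rng: np.random.Generator, n: int, rid: str, q: int = 40) -> Read:
    bases = "".join(rng.choice(list("ACGT"), size=n))
    return Read(id=rid, bases=bases, quals=[q] * n)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """5 error-free transcripts at 200x with 150 bp truncations."""
    cfg = SimConfig(n_transcripts=5, len_min=900, len_max=1500, coverage=200,
                    err=0.0, het=0.0, seed=3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_store(small_sim):
    return build_store(small_sim.reads)
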