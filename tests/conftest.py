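import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svref.fixtures import build_experiment

settings.register_profile(
    "svref",
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("svref")

logging.getLogger("svref.fixtures").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20120501)


@pytest.fixture(scope="session")
def table1_exp():
    """The 20-SV benchmark experiment (shared: the k-mer index is the
    expensive part)."""
    exp = build_experiment("table1", seed=1)
    exp.ref_kmer_counts  # force the index once
    return exp


@pytest.fixture(scope="session")
def minimal_exp():
    exp = build_experiment("minimal", seed=3)
    exp.ref_kmer_counts
    return exp


@pytest.fixture(scope="session")
def germline_exp():
    exp = build_experiment("germline-demo", seed=5)
    exp.ref_kmer_counts
    return exp


def random_genome(rng, sizes: dict[str, int]):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        name: bytes(bases[rng.integers(0, 4, size=n, dtype=np.uint8)]).decode()
        for name, n in sizes.items()
    }
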