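import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import methdirect as md

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def genome20k():
    return md.random_genome(20_000, 1234)


@pytest.fixture(scope="session")
def index20k(genome20k):
    return md.build_index(genome20k)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
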