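import numpy as np
import pytest

from estuarybin.synthetic import CommunityConfig, simulate_community

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@pytest.fixture(scope="session")
def small_community():
    """Four moderately divergent genomes, two libraries, light sequencing.

    Shared across tests that only need a realistic community structure, not
    a specific study condition.
    """
    cfg = CommunityConfig(
        n_genomes=4,
        genome_length=120_000,
        divergence=0.5,
        reads_per_library=30_000,
        n_markers=24,
        seed=42,
    )
    return simulate_community(cfg)
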