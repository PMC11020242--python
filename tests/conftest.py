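import numpy as np
import pytest

from sexmer import GenomeConfig, KmerSpec, generate_genome


@pytest.fixture(scope="session")
def spec21() -> KmerSpec:
    return KmerSpec(21)


@pytest.fixture(scope="session")
def small_truth():
    """A small three-chromosome truth genome shared by read-level tests."""
    cfg = GenomeConfig(
        autosome_len=200_000, x_len=80_000, y_len=20_000, par_len=2_000,
        xy_divergence=0.01, seed=11,
    )
    return generate_genome(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), n))
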