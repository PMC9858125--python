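import numpy as np
import pytest

from embryogeny.config import GAConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A fast config for structural tests: small population, short genome."""
    return GAConfig(population_size=10, genome_length=8, gene_value_range=(1, 8),
                    generations=5, seed=7)


def brute_force_inversions(seq) -> int:
    """O(L^2) pair enumeration; the independent oracle for inversion counts."""
    seq = list(seq)
    return sum(
        1
        for i in range(len(seq))
        for j in range(i + 1, len(seq))
        if seq[i] > seq[j]
    )
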