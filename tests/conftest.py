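import numpy as np
import pytest

from driftwatch import GenotypeMatrix, PopulationMap


def make_matrix(calls, sample_prefix="s", locus_prefix="L"):
    """GenotypeMatrix from a nested list [(a,b), ...] per sample per locus."""
    calls = np.asarray(calls, dtype=np.int16)
    return GenotypeMatrix(
        [f"{sample_prefix}{i + 1}" for i in range(calls.shape[0])],
        [f"{locus_prefix}{j + 1}" for j in range(calls.shape[1])],
        calls,
    )


@pytest.fixture
def two_pop_toy():
    """2 populations x 3 individuals, 2 biallelic loci, moderate divergence."""
    calls = [
        [(0, 0), (0, 1)],
        [(0, 1), (0, 0)],
        [(0, 0), (0, 0)],
        [(1, 1), (1, 1)],
        [(0, 1), (1, 1)],
        [(1, 1), (0, 1)],
    ]
    g = make_matrix(calls)
    pm = PopulationMap({f"s{i + 1}": ("A" if i < 3 else "B") for i in range(6)})
    return g, pm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
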