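import numpy as np
import pandas as pd
import pytest

from oomics import simulate


@pytest.fixture(scope="session")
def genome():
    """Default desk-scale genome (3 x 5 Mb), shared across tests."""
    return simulate.make_genome(seed=7)


@pytest.fixture(scope="session")
def small_genome():
    return simulate.make_genome(
        sizes={"chr1": 1_000_000}, n_genes=10, n_cgis=10, n_ervs=6, seed=7
    )


@pytest.fixture(scope="session")
def chip_data(genome):
    """Planted-domain ChIP simulation with artifact windows."""
    domains = simulate.plant_domains(genome, seed=3)
    windows, counts, truth = simulate.simulate_chip(
        genome, domains, n_artifact_windows=20, seed=5
    )
    return windows, counts, truth, domains


def random_intervals(rng, n, chrom="chr1", span=100_000):
    starts = rng.integers(0, span - 1, size=n)
    lengths = rng.integers(1, 5_000, size=n)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": np.minimum(starts + lengths, span)}
    )
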