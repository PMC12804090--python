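import numpy as np
import pandas as pd
import pytest

from nucleome.layout import make_genome
from nucleome.simdata import (
    NuclearGeometry,
    plant_truth,
    simulate_structures,
)


@pytest.fixture(scope="session")
def small_layout():
    """Two chromosomes, 50 + 25 bins at 200 kb."""
    return make_genome([10_000_000, 5_000_000], 200_000)


@pytest.fixture(scope="session")
def one_chrom_500():
    """One 100-Mb chromosome at 200 kb: 500 bins."""
    return make_genome([100_000_000], 200_000)


@pytest.fixture(scope="session")
def small_population(small_layout):
    truth = plant_truth(small_layout, block_bins=5, tad_bins=10)
    geom = NuclearGeometry.sphere(5000.0)
    return simulate_structures(small_layout, geom, truth, n_structures=20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_matrix(rng, layout, scale=10.0):
    """Symmetric non-negative random count matrix on a layout."""
    n = layout.n_bins
    m = rng.poisson(scale, size=(n, n)).astype(float)
    m = np.triu(m) + np.triu(m, 1).T
    return m


@pytest.fixture()
def toy_loops():
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start1": [1_000_000, 2_000_000, 4_000_000],
            "end1": [1_010_000, 2_010_000, 4_010_000],
            "start2": [1_500_000, 2_600_000, 4_900_000],
            "end2": [1_510_000, 2_610_000, 4_910_000],
        }
    )
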