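import numpy as np
import pandas as pd
import pytest

from fulmargsi.io_formats import GENOTYPE_COLUMNS, GenotypeTable
from fulmargsi.synthetic_data import SimulationConfig, simulate_bundle


def genotype_table(rows):
    """Build a GenotypeTable from (sample, locus, a1, a2[, d1, d2]) tuples."""
    cols = GENOTYPE_COLUMNS[:len(rows[0])]
    return GenotypeTable(pd.DataFrame(rows, columns=cols))


@pytest.fixture(scope="session")
def small_bundle():
    """A small but structured bundle: strong drift so assignment works."""
    cfg = SimulationConfig(n_loci=50, fst=0.05, ref_sizes=(40, 40, 40, 40),
                           mixture_size=150, seed=1234)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def two_colony_bundle():
    cfg = SimulationConfig(
        n_colonies=2, fst=0.05, n_loci=40, ref_sizes=(60, 60),
        mixture_size=5, mixture_proportions=(0.6, 0.4),
        colony_names=("East", "West"),
        colony_centroids=((56.0, -160.0), (58.0, -170.0)),
        census_sizes=(1000, 1000), census_percents=(50, 50), seed=77)
    return simulate_bundle(cfg)
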