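"""Shared fixtures: toy graphs and a session-scoped grid simulation."""

import numpy as np
import pytest

from spc import gridsim
from spc.io_core import GenotypeMatrix, SampleTable
import pandas as pd


def make_genotypes(dosages, positions=None, chromosome=1, sample_ids=None):
    """GenotypeMatrix from a samples x variants int array."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chromosome": np.full(m, chromosome),
            "position": np.asarray(positions),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "id": [f"v{j}" for j in range(m)],
        }
    )
    return GenotypeMatrix(
        samples=SampleTable(sample_ids), variants=variants, dosages=d
    )


@pytest.fixture(scope="session")
def sim_small():
    """A modest 4x4 grid run shared by simulation-dependent unit tests.

    40 diploids per deme on a 30 Mb chromosome: large enough for the
    spatial-decay and F_ST invariants, small enough to run in well under a
    minute.
    """
    config = gridsim.DemeGridConfig(
        grid_n=4,
        diploids_per_deme=40,
        chromosomes=((30_000_000, 1.149e-8),),
        seed=20240917,
    )
    return gridsim.simulate_grid(config)


@pytest.fixture(scope="session")
def sim_small_pairs(sim_small):
    from spc.ibd_graph import aggregate_pairwise

    return aggregate_pairwise(gridsim.extract_true_ibd(sim_small, min_cM=3.0))
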