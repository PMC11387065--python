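import numpy as np
import pandas as pd
import pytest

from dietshift import CommunityConfig, DietTable, generate_diet_table
from dietshift.allometry import SubsampleDesign


def make_table(counts, species=None, season=None, ids=None, taxa=None):
    """Small hand-built diet table for unit tests."""
    counts = np.atleast_2d(np.asarray(counts))
    n = counts.shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    taxa = taxa or [f"t{j}" for j in range(counts.shape[1])]
    species = species or ["elk"] * n
    season = season or ["summer"] * n
    meta = pd.DataFrame(
        {
            "species": species,
            "season": season,
            "herd": [f"h{i}" for i in range(n)],
            "date": pd.Timestamp("2017-07-01"),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return DietTable(
        pd.DataFrame(counts, index=meta.index, columns=taxa), meta
    )


@pytest.fixture(scope="session")
def small_config():
    """Compact community: 3 samples per cell, fewer taxa, shallow reads."""
    cells = {
        (sp, se): 4
        for sp in ("pronghorn", "bighorn_sheep", "mule_deer", "elk", "bison")
        for se in ("summer", "winter")
    }
    return CommunityConfig(samples_per_cell=cells, n_taxa=300, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    table, annot = generate_diet_table(small_config)
    return table, annot, small_config


@pytest.fixture(scope="session")
def paper_scale_dataset():
    cfg = CommunityConfig(seed=5)
    table, annot = generate_diet_table(cfg)
    return table, annot, cfg


@pytest.fixture()
def design():
    return SubsampleDesign(n_per_cell=4, n_reps=5, seed=99)
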