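import numpy as np
import pandas as pd
import pytest

from villagefactor.simulate import (
    OutlierSpec,
    VillageConfig,
    simulate_village,
)


@pytest.fixture(scope="session")
def village_sim():
    """Reference study conditions: two 20-donor villages, three cell types,
    two planted aberrant donors, 5% doublets."""
    cfg = VillageConfig(outliers=OutlierSpec(n_outliers=2))
    return simulate_village(cfg, seed=11)


@pytest.fixture(scope="session")
def village_counts_df(village_sim):
    sim = village_sim
    return pd.DataFrame(
        sim.counts.toarray(), index=sim.gene_ids, columns=sim.nuclei["barcode"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
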