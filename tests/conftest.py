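import numpy as np
import pandas as pd
import pytest

from omicsfuse.containers import CONTINUOUS, COUNTS, OmicsBlock
from omicsfuse.simulate import SimulationConfig, generate_dataset, generate_gene_sets


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort that keeps all planted roles (5 clusters)."""
    return SimulationConfig(
        cluster_sizes=(8, 6, 8, 6, 5),
        n_healthy=6,
        n_genes=150,
        n_somascan=80,
        n_shotgun=70,
        n_taxa_16s=60,
        n_taxa_meta=70,
        marker_genes_per_cluster=10,
        marker_proteins_per_cluster=10,
        quad_set_size=10,
        indicator_taxa_per_cluster=5,
        n_decoy_sets=10,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size study conditions: 20/12/18/12/10 clusters, 13 healthy."""
    return generate_dataset(SimulationConfig(rng_seed=5))


@pytest.fixture(scope="session")
def small_gene_sets(small_config):
    return generate_gene_sets(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_block(values, kind=CONTINUOUS, name="block", features=None, subjects=None):
    values = np.asarray(values)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    subjects = subjects or [f"s{j}" for j in range(values.shape[1])]
    return OmicsBlock(name, kind, pd.DataFrame(values, index=features, columns=subjects))
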