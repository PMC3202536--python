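import numpy as np
import pytest

from mirconnect.correlate import correlate_panel
from mirconnect.data import detectability_filter
from mirconnect.synthetic import SyntheticConfig, generate


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast panel for module tests: full 59-sample depth, few genes."""
    defaults = dict(
        n_mirnas=18,
        n_genes=600,
        singleton_pool_size=300,
        n_suppressed_per_mirna=10,
        n_platforms=2,
        probes_per_gene=(1, 2),
    )
    defaults.update(overrides)
    return SyntheticConfig(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config(seed=0))


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    ds = small_dataset
    profiles = detectability_filter(
        ds.mirna_matrix, limit=ds.config.detection_limit, min_samples=30
    )
    return correlate_panel(
        profiles, ds.mrna_matrices, ds.probe_map, ds.mirna_matrix.sample_ids,
        methods=("spcc", "dpcc"), seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
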