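import numpy as np
import pytest
from hypothesis import settings

import atlasinfer as ai

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_atlas():
    """Default synthetic atlas (seed 1) shared across recovery tests."""
    ds = ai.simulate_dataset(ai.SimConfig(seed=1))
    labels = ds.cell_labels.loc[ds.cells].to_numpy()
    return ds, labels


@pytest.fixture(scope="session")
def default_profile(default_atlas):
    """Bootstrap profile of the default atlas (reduced replicate count
    keeps the suite fast; CIs are only consumed as robust/not-robust)."""
    ds, labels = default_atlas
    return ai.bootstrap_profile(
        ds.counts, labels, n_boot=300, seed=3, genes=ds.genes, cell_names=ds.cells
    )


@pytest.fixture(scope="session")
def small_config():
    """A miniature generator configuration for pipeline-level tests."""
    return dict(
        n_cell_types=6,
        cells_per_type=40,
        n_genes=300,
        n_housekeeping=30,
        n_markers_per_type=5,
        n_tfs=8,
        targets_per_tf=6,
        n_lr_pairs=20,
        n_signatures=1,
        lr_pairs_per_signature=4,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
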