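import numpy as np
import pytest

import scmosaic as sm


@pytest.fixture(scope="session")
def small_dataset():
    """Small tri-modal dataset with ground truth, shared across tests."""
    ds, gt = sm.simulate(sm.SimConfig(
        n_cells=300, n_genes=60, n_regions=80, n_proteins=8,
        n_types=3, n_batches=2, seed=11))
    return ds, gt


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A briefly trained model on the small dataset (smoke-scale)."""
    ds, _ = small_dataset
    mc = sm.ModelConfig(latent_dim=8, n_hidden=32, dropout=0.0, seed=0)
    tc = sm.TrainConfig(max_epochs=30, patience=30, batch_size=128, seed=0)
    model, state = sm.fit(ds, mc, tc)
    return model, state


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
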