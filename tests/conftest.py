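import numpy as np
import pytest

from bfreg.hierarchy import BioHierarchy
from bfreg.synthetic import gen_cohort, gen_hierarchy


@pytest.fixture(scope="session")
def small_hierarchy():
    return gen_hierarchy(12, 8, 3, edge_density=0.2, n_modules=1, module_size=5, seed=7)


@pytest.fixture(scope="session")
def small_bio_hierarchy(small_hierarchy):
    return BioHierarchy.from_true_hierarchy(small_hierarchy)


@pytest.fixture(scope="session")
def small_cohort(small_hierarchy):
    return gen_cohort(
        n_tumor=80, n_normal=30, n_genes=12, n_deg=4, n_prognostic=5, seed=7,
        prognostic_genes=small_hierarchy.planted_modules[0],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_study():
    """The default planted-module study: hierarchy, cohort and trained model.

    One 10-gene prognostic module in a 50-gene hierarchy, n_tumor = 500,
    seed 42, trained with the optimizer schedule scaled to 50 epochs.
    Trained once per session; used by every test that needs the fitted
    network.
    """
    from bfreg.network import TrainConfig, train_model

    hier = gen_hierarchy(n_genes=50, n_proteins=30, n_pathways=8, seed=42)
    bh = BioHierarchy.from_true_hierarchy(hier)
    cohort = gen_cohort(n_tumor=500, n_normal=100, n_genes=50, n_deg=10,
                        n_prognostic=10, seed=42,
                        prognostic_genes=hier.planted_modules[0])
    model = train_model(bh, cohort, TrainConfig.scaled_to(max_epochs=50, seed=42))
    return hier, bh, cohort, model
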