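import numpy as np
import pandas as pd
import pytest

from pseudomut import PipelineConfig, TP53ClassifierModel
from pseudomut.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions with a clear planted signal."""
    return SyntheticConfig(
        n_wt=120, n_mut=40, n_pm=6, n_normal=20,
        n_probes=300, n_informative=20, delta=2.0,
        n_pathways=3, n_noise_pathways=1, pathway_size=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clf_config():
    """Classifier-focused conditions: moderate planted signal, no pathway
    blocks, so the informative probes are the only wt/mut difference."""
    return SyntheticConfig(
        n_wt=150, n_mut=45, n_pm=8, n_normal=0,
        n_probes=300, n_informative=20, delta=1.2,
        n_pathways=0, n_noise_pathways=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clf_dataset(clf_config):
    return generate_dataset(clf_config)


@pytest.fixture(scope="session")
def fitted(clf_dataset):
    """A full pipeline fit on the classifier cohort (shared; read-only)."""
    model = TP53ClassifierModel(
        clf_dataset.em, clf_dataset.cohort,
        config=PipelineConfig(n_iter=12, c_min=9, k_max=25),
    )
    return model.fit(seed=11)


@pytest.fixture()
def toy_expression():
    """A tiny handmade expression frame (3 probes x 4 samples)."""
    return pd.DataFrame(
        [[1.2, 0.8, 3.1, 2.9], [5.0, 5.1, 4.9, 5.2], [2.0, 1.0, 2.0, 1.0]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
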