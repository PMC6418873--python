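import numpy as np
import pytest

from dticnn import nn
from dticnn import model as pcnn
from dticnn import prep
from dticnn import synthetic as syn

nn.configure_malloc()


@pytest.fixture(scope="session")
def small_atlas():
    return syn.generate_atlas((24, 28, 24), n_gray=6, n_white=4, seed=7)


@pytest.fixture(scope="session")
def tiny_atlas():
    return syn.generate_atlas((12, 12, 12), n_gray=3, n_white=1, seed=5)


@pytest.fixture(scope="session")
def separable_store():
    """Two constant-intensity classes plus mild noise: linearly separable."""
    rng = np.random.default_rng(0)
    n = 20
    vols = np.empty((n, 12, 12, 12), np.float32)
    groups = []
    for i in range(n):
        g = "A" if i % 2 == 0 else "B"
        vols[i] = (0.7 if g == "A" else 0.3) + rng.normal(0, 0.05, (12, 12, 12))
        groups.append(g)
    return prep.PreparedDataset.from_groups(vols, groups)


@pytest.fixture(scope="session")
def trained_tiny_model(separable_store):
    store = separable_store
    cfg = pcnn.TrainingConfig(epochs=5, seed=1, batch_size=8)
    model = pcnn.build_model(store.target_shape, cfg)
    labels = store.labels.astype(np.float32)
    model, history = pcnn.train(
        model, store.volumes[:16], labels[:16], store.volumes[16:], labels[16:], cfg
    )
    return model, history, store


@pytest.fixture(scope="session")
def null_cohort_store():
    """Labels independent of content: no injected effects."""
    spec = syn.CohortSpec(
        n_subjects=60, volume_shape=(12, 12, 12), effects=[],
        n_gray_rois=4, n_white_rois=2, seed=11,
    )
    vols, groups, atlas = syn.render_cohort_volumes(spec)
    return prep.PreparedDataset.from_groups(vols, groups), atlas
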