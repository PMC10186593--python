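import numpy as np
import pytest

from iscaging import SimConfig, generate_cohort
from iscaging.preprocess import cluster, embed, normalize, qc_filter


SMALL = dict(n_cells_per_mouse=150, n_genes=1400)


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort shared by read-only tests."""
    cfg = SimConfig(seed=7, **SMALL)
    counts, meta, truth = generate_cohort(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def processed(small_cohort):
    counts, meta, truth = small_cohort
    kept, _ = qc_filter(counts)
    norm = normalize(kept)
    emb = embed(norm, n_components=20)
    labels = cluster(emb, seed=0)
    return kept, norm, emb, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
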