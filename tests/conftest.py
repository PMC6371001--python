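import numpy as np
import pytest

from deltaomics import generate_mini


@pytest.fixture(scope="session")
def mini():
    """Seeded mini study at the study's cohort size (27 subjects)."""
    blocks, truth = generate_mini(seed=1)
    return blocks, truth


@pytest.fixture(scope="session")
def mini_big():
    """Mini feature counts at n=200 for structure-recovery checks."""
    blocks, truth = generate_mini(seed=7, n_subjects=200, sigma=0.3)
    return blocks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def planted_matrix(blocks, truth):
    """Data matrix over the planted features (truth order)."""
    frames = {b.name: b.to_frame() for b in blocks}
    owner = {f: b.name for b in blocks for f in b.features}
    ids = truth.planted_features()
    X = np.column_stack([frames[owner[f]][f].to_numpy() for f in ids])
    classes = {f: owner[f] for f in ids}
    return X, ids, classes
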