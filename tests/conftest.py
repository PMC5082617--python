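import numpy as np
import pytest

from gragp.data_io import CountMatrix, LabelVector
from gragp.simulate import SimConfig, simulate_counts


@pytest.fixture
def small_counts():
    """3 genes x 4 samples with a hand-checkable layout."""
    counts = np.array(
        [
            [0, 1, 2, 3],
            [4, 5, 6, 7],
            [8, 9, 10, 11],
        ]
    )
    return CountMatrix(counts, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def small_labels():
    return LabelVector(np.array([0, 0, 1, 1]), ("A", "B"))


@pytest.fixture(scope="session")
def sim_study():
    """A modest overdispersed study with planted signal, shared across tests."""
    cfg = SimConfig(
        n_genes=200,
        n_per_class=(12, 12),
        de_fraction=0.05,
        log2_fold_change=2.0,
        dispersion=0.2,
        seed=42,
    )
    return simulate_counts(cfg)
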