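import numpy as np
import pytest

from bsvm.data_model import GenotypeDataset


def make_dataset(case_cols, ctrl_cols, variant_ids=None):
    """Build a GenotypeDataset from per-group genotype matrices
    (lists of rows, one column per variant)."""
    case = np.asarray(case_cols)
    ctrl = np.asarray(ctrl_cols)
    counts = np.vstack([case, ctrl])
    labels = np.concatenate([np.ones(case.shape[0], dtype=np.int8),
                             -np.ones(ctrl.shape[0], dtype=np.int8)])
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(counts.shape[1])]
    return GenotypeDataset(counts, labels, variant_ids)


@pytest.fixture
def toy_separable():
    """10 cases all carrying a risk allele, 10 controls carrying none,
    plus a second variant that is pure noise."""
    rng = np.random.default_rng(5)
    case = np.column_stack([np.ones(10, int), rng.integers(0, 2, 10)])
    ctrl = np.column_stack([np.zeros(10, int), rng.integers(0, 2, 10)])
    return make_dataset(case, ctrl)


@pytest.fixture
def random_null_dataset():
    """Labels independent of genotypes: 100 cases / 100 controls over
    8 variants at assorted frequencies."""
    rng = np.random.default_rng(17)
    counts = rng.binomial(2, np.linspace(0.02, 0.3, 8), size=(200, 8))
    labels = np.concatenate([np.ones(100, np.int8), -np.ones(100, np.int8)])
    return GenotypeDataset(counts, labels, [f"v{j}" for j in range(8)])
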