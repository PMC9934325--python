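import numpy as np
import pytest

from conncf import ExpressionTensor


def make_tensor(n_drugs, n_cells, n_genes, seed=0, missing_fraction=0.0):
    """Random dense tensor with an optional fraction of unobserved pairs.

    Missing pairs are chosen so every drug keeps >= 2 observed cells and
    every cell >= 2 observed drugs.
    """
    rng = np.random.default_rng(seed)
    drugs = [f"d{i:03d}" for i in range(n_drugs)]
    cells = [f"c{j:02d}" for j in range(n_cells)]
    genes = [f"g{k:03d}" for k in range(n_genes)]
    values = rng.normal(size=(n_drugs, n_cells, n_genes))
    observed = np.ones((n_drugs, n_cells), dtype=bool)
    if missing_fraction > 0:
        flat = rng.permutation(n_drugs * n_cells)
        target = int(missing_fraction * flat.size)
        removed = 0
        for idx in flat:
            if removed >= target:
                break
            i, j = divmod(idx, n_cells)
            observed[i, j] = False
            if observed[i].sum() < 2 or observed[:, j].sum() < 2:
                observed[i, j] = True
            else:
                removed += 1
        values = np.where(observed[:, :, None], values, np.nan)
    return ExpressionTensor(drugs, cells, genes, values, observed)


@pytest.fixture
def small_tensor():
    return make_tensor(6, 4, 20, seed=42)


@pytest.fixture
def sparse_tensor():
    return make_tensor(10, 5, 20, seed=7, missing_fraction=0.4)
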