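"""Impute missing (drug, cell) expression profiles.

Four methods, from naive to latent-factor:

* tissue-agnostic (TA): per-gene median of the drug over all other cells;
* median of medians (MoM): mean of the drug's cross-cell median and the
  cell's cross-drug median, per gene;
* neighborhood collaborative filtering (NCF): similarity-weighted average of
  the most similar drugs' profiles in the target cell, with adjusted-cosine
  similarity computed on the reshaped drugs x (cells*genes) matrix
  excluding the target cell's columns;
* FunkSVD: regularized low-rank factorization fitted by stochastic gradient
  descent over observed entries only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionTensor, ReshapedMatrix, reshape_tensor

try:  # optional JIT for the SGD inner loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

__all__ = [
    "ImputationError",
    "ConvergenceError",
    "NCFParams",
    "SVDParams",
    "FunkSVDModel",
    "impute_tissue_agnostic",
    "impute_mom",
    "drug_similarity",
    "impute_ncf",
    "funk_svd_fit",
    "funk_svd_predict",
    "default_k_neighbors",
]

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    """A method cannot produce a prediction for the requested pair."""


class ConvergenceError(RuntimeError):
    """SGD training diverged (RMSE became non-finite)."""


def default_k_neighbors(n_drugs: int) -> int:
    """Default neighborhood size: ten percent of the drugs, rounded up."""
    return max(1, math.ceil(0.10 * n_drugs))


@dataclass
class NCFParams:
    """Neighborhood collaborative filtering settings.

    ``k_neighbors=None`` means ceil(0.10 * n_drugs).  ``min_overlap`` is the
    number of co-observed columns required before a similarity is defined.
    ``exclude_negative`` optionally drops negatively-similar neighbors from
    the top-k selection.
    """

    k_neighbors: int | None = None
    min_overlap: int = 10
    exclude_negative: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors is not None and self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class SVDParams:
    """FunkSVD hyperparameters; only ``rank`` is method-critical."""

    rank: int = 55
    learning_rate: float = 0.001
    regularization: float = 0.015
    max_epochs: int = 200
    tol: float = 1e-4
    seed: int = 0
    init_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def impute_tissue_agnostic(
    tensor: ExpressionTensor, drug: str, cell: str
) -> np.ndarray:
    """Per-gene median of the drug's profiles over all other observed cells."""
    i = tensor.drug_index(drug)
    j = tensor.cell_index(cell)
    others = np.flatnonzero(tensor.observed[i])
    others = others[others != j]
    if others.size == 0:
        raise ImputationError(
            f"drug {drug!r} is not observed in any cell other than {cell!r}"
        )
    return np.median(tensor.values[i, others, :], axis=0)


def impute_mom(tensor: ExpressionTensor, drug: str, cell: str) -> np.ndarray:
    """Median of the drug's cross-cell median and the cell's cross-drug median.

    The median of two values is their mean, so the result is the average of
    the tissue-agnostic row prediction and the drug-agnostic column
    prediction, per gene.
    """
    i = tensor.drug_index(drug)
    j = tensor.cell_index(cell)
    other_cells = np.flatnonzero(tensor.observed[i])
    other_cells = other_cells[other_cells != j]
    other_drugs = np.flatnonzero(tensor.observed[:, j])
    other_drugs = other_drugs[other_drugs != i]
    if other_cells.size == 0:
        raise ImputationError(
            f"drug {drug!r} is not observed in any cell other than {cell!r}"
        )
    if other_drugs.size == 0:
        raise ImputationError(
            f"cell {cell!r} is not observed for any drug other than {drug!r}"
        )
    row_median = np.median(tensor.values[i, other_cells, :], axis=0)
    col_median = np.median(tensor.values[other_drugs, j, :], axis=0)
    return (row_median + col_median) / 2.0


# ---------------------------------------------------------------------------
# neighborhood collaborative filtering
# ---------------------------------------------------------------------------

def drug_similarity(
    R: ReshapedMatrix,
    params: NCFParams | None = None,
    exclude_cell: str | None = None,
) -> np.ndarray:
    """Adjusted-cosine similarity between drug rows of the reshaped matrix.

    Each row is mean-centered over its observed entries, then the cosine is
    taken over the columns observed in *both* rows.  Pairs with fewer than
    ``min_overlap`` co-observed columns are undefined and returned as NaN.
    ``exclude_cell`` drops that cell's column block (and its contribution to
    row centering) before anything is computed, which is how leakage from
    the target cell is avoided during imputation.
    """
    params = params or NCFParams()
    if len(R.drugs) < 2:
        raise ValueError("need at least 2 drugs to compute similarities")
    col_mask = R.column_mask()
    vals = R.values.copy()
    if exclude_cell is not None:
        block = R.column_block(exclude_cell)
        keep = np.ones(vals.shape[1], dtype=bool)
        keep[block] = False
        vals = vals[:, keep]
        col_mask = col_mask[:, keep]
    vals = np.where(col_mask, vals, 0.0)
    counts = col_mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_means = np.where(counts > 0, vals.sum(axis=1) / counts, 0.0)
    centered = np.where(col_mask, vals - row_means[:, None], 0.0)
    w = col_mask.astype(float)
    overlap = w @ w.T
    num = centered @ centered.T
    sq = centered**2
    norm2 = sq @ w.T  # norm2[i, j] = ||centered_i restricted to obs_j||^2
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = num / np.sqrt(norm2 * norm2.T)
    sim[overlap < params.min_overlap] = np.nan
    # a defined self-similarity is exactly 1
    diag_ok = np.diag(overlap) >= params.min_overlap
    sim[np.diag_indices_from(sim)] = np.where(diag_ok, 1.0, np.nan)
    return sim


def impute_ncf(
    R: ReshapedMatrix,
    drug: str,
    cell: str,
    params: NCFParams | None = None,
    similarities: np.ndarray | None = None,
) -> np.ndarray:
    """Similarity-weighted average of neighbor profiles in the target cell.

    Neighbors must be observed in the target cell and have a defined
    similarity to the target drug (computed excluding the target cell's
    columns).  The top ``k_neighbors`` by signed similarity are combined as
    ``sum(sim * value) / sum(|sim|)`` per gene.
    """
    params = params or NCFParams()
    i = R._di[drug]
    j = R._ci[cell]
    if similarities is None:
        similarities = drug_similarity(R, params, exclude_cell=cell)
    sims = similarities[i]
    candidates = np.flatnonzero(
        R.observed[:, j] & np.isfinite(sims) & (np.arange(len(R.drugs)) != i)
    )
    if params.exclude_negative:
        candidates = candidates[sims[candidates] > 0]
    if candidates.size == 0:
        raise ImputationError(
            f"no eligible neighbor for ({drug!r}, {cell!r}): need a drug "
            "observed in the target cell with a defined similarity"
        )
    k = params.k_neighbors or default_k_neighbors(len(R.drugs))
    order = np.argsort(-sims[candidates], kind="stable")
    chosen = candidates[order[:k]]
    weights = sims[chosen]
    denom = np.abs(weights).sum()
    if denom == 0:
        raise ImputationError(
            f"all selected neighbor similarities are zero for ({drug!r}, {cell!r})"
        )
    block = R.column_block(j)
    neigh_vals = R.values[chosen, block]
    logger.debug(
        "ncf %s/%s: %d candidates, %d used, sim range [%.3f, %.3f]",
        drug, cell, candidates.size, chosen.size,
        weights.min(), weights.max(),
    )
    return (weights[:, None] * neigh_vals).sum(axis=0) / denom


# ---------------------------------------------------------------------------
# FunkSVD
# ---------------------------------------------------------------------------

def _sgd_epoch_python(U, V, rows, cols, vals, lr, reg):
    se = 0.0
    rank = U.shape[1]
    for t in range(rows.shape[0]):
        i = rows[t]
        j = cols[t]
        pred = 0.0
        for f in range(rank):
            pred += U[i, f] * V[j, f]
        e = vals[t] - pred
        se += e * e
        for f in range(rank):
            uif = U[i, f]
            U[i, f] += lr * (e * V[j, f] - reg * uif)
            V[j, f] += lr * (e * uif - reg * V[j, f])
    return se


if _HAVE_NUMBA:
    _sgd_epoch = _njit(cache=True)(_sgd_epoch_python)
else:  # pragma: no cover
    _sgd_epoch = _sgd_epoch_python


@dataclass(eq=False)
class FunkSVDModel:
    """Fitted factors plus the training-RMSE trace."""

    drugs: list[str]
    cells: list[str]
    genes: list[str]
    U: np.ndarray  # (n_drugs, rank)
    V: np.ndarray  # (n_cells*n_genes, rank)
    rmse_trace: list[float]
    params: SVDParams

    def predict_profile(self, drug: str, cell: str) -> np.ndarray:
        i = self.drugs.index(drug)
        j = self.cells.index(cell)
        g = len(self.genes)
        block = slice(j * g, (j + 1) * g)
        return self.U[i] @ self.V[block].T

    def reconstruct(self) -> np.ndarray:
        return self.U @ self.V.T


def funk_svd_fit(R: ReshapedMatrix, params: SVDParams | None = None) -> FunkSVDModel:
    """Fit rank-``k`` factors by SGD over observed entries only.

    Entries are visited in a freshly shuffled order each epoch (seeded, so a
    given seed yields a bit-identical trajectory).  Training stops when the
    epoch RMSE improves by less than ``tol`` or ``max_epochs`` is reached.
    """
    params = params or SVDParams()
    col_mask = R.column_mask()
    rows, cols = np.nonzero(col_mask)
    if rows.size == 0:
        raise ValueError("matrix has no observed entries")
    if params.rank > min(R.values.shape):
        raise ValueError(
            f"rank {params.rank} exceeds min(matrix shape) {min(R.values.shape)}"
        )
    vals = R.values[rows, cols]
    rng = np.random.default_rng(params.seed)
    s = params.init_scale
    U = rng.uniform(-s, s, size=(R.values.shape[0], params.rank))
    V = rng.uniform(-s, s, size=(R.values.shape[1], params.rank))
    trace: list[float] = []
    prev = np.inf
    for _ in range(params.max_epochs):
        order = rng.permutation(rows.size)
        se = _sgd_epoch(
            U, V, rows[order], cols[order], vals[order],
            params.learning_rate, params.regularization,
        )
        rmse = float(np.sqrt(se / rows.size))
        if not np.isfinite(rmse):
            raise ConvergenceError(
                "training RMSE diverged; try a smaller learning_rate"
            )
        trace.append(rmse)
        if prev - rmse < params.tol:
            break
        prev = rmse
    return FunkSVDModel(
        list(R.drugs), list(R.cells), list(R.genes), U, V, trace, params
    )


def funk_svd_predict(model: FunkSVDModel, drug: str, cell: str) -> np.ndarray:
    """Slice of the rank-k reconstruction for the target (drug, cell) block."""
    return model.predict_profile(drug, cell)


def impute_svd(
    tensor: ExpressionTensor, drug: str, cell: str, params: SVDParams | None = None
) -> np.ndarray:
    """Convenience wrapper: fit FunkSVD on the reshaped tensor and predict."""
    model = funk_svd_fit(reshape_tensor(tensor), params)
    return funk_svd_predict(model, drug, cell)
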