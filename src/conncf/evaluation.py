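"""Cross-validation machinery and the head-weighted rank-agreement metric.

Fold assignment is uniform-random over observed (drug, cell) pairs subject
to a balance constraint: no fold may hold more than 75% of a drug's
observed cells or of a cell's observed drugs (exactly 75% is allowed).
Violating candidates are discarded and regenerated whole, never repaired.

The agreement metric (``weighted_spearman``) is a weighted Pearson
correlation of rank vectors with Gaussian weights anchored at the ranks of
the *true* result list: ``w(r) = 2 * phi(r | mu=0, sigma=n*epsilon)``.
With ``epsilon = 0.01`` and a few hundred results, only roughly the top 20
positions carry appreciable weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import RankedProfile, _wcs_on_ranked, DEFAULT_WEIGHT_EXPONENT
from .data_model import ExpressionTensor, extract_signature, reshape_tensor
from .imputation import (
    ImputationError,
    NCFParams,
    SVDParams,
    drug_similarity,
    funk_svd_fit,
    funk_svd_predict,
    impute_mom,
    impute_ncf,
    impute_tissue_agnostic,
)

__all__ = [
    "FoldAssignment",
    "WSpeParams",
    "assign_folds",
    "run_cross_validation",
    "weighted_spearman",
    "score_connectivity_agreement",
    "downsample",
]

logger = logging.getLogger(__name__)

N_FOLDS = 5
MAX_FOLD_FRACTION = 0.75
DOWNSAMPLE_FRACTIONS = (0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass
class FoldAssignment:
    """Map (drug, cell) -> fold in 1..n_folds; 0 marks missing pairs."""

    drugs: list[str]
    cells: list[str]
    folds: np.ndarray  # (n_drugs, n_cells) int, 0 = unobserved
    n_folds: int
    seed: int
    attempts: int
    run_id: int = 1

    def fold_of(self, drug: str, cell: str) -> int:
        return int(
            self.folds[self.drugs.index(drug), self.cells.index(cell)]
        )

    def pairs_in_fold(self, fold: int) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(self.folds == fold)
        return [(self.drugs[i], self.cells[j]) for i, j in zip(ii, jj)]

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.folds > 0)
        return pd.DataFrame(
            {
                "drug": [self.drugs[i] for i in ii],
                "cell": [self.cells[j] for j in jj],
                "fold": self.folds[ii, jj],
            }
        )


@dataclass
class WSpeParams:
    epsilon: float = 0.01
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


def _fold_counts_ok(folds: np.ndarray, observed: np.ndarray, n_folds: int) -> bool:
    # constraint: count <= 0.75 * n_observed, i.e. 4*count <= 3*n_observed
    for axis in (1, 0):
        n_obs = observed.sum(axis=axis)
        for f in range(1, n_folds + 1):
            counts = (folds == f).sum(axis=axis)
            if np.any(4 * counts > 3 * n_obs):
                return False
    return True


def assign_folds(
    tensor: ExpressionTensor,
    seed: int,
    n_folds: int = N_FOLDS,
    max_attempts: int = 10_000,
    run_id: int = 1,
) -> FoldAssignment:
    """Constrained uniform-random fold assignment over observed pairs.

    Requires every drug to be observed in at least 2 cells and every cell
    for at least 2 drugs.  Candidate assignments violating the 75% balance
    rule are regenerated from scratch, up to ``max_attempts`` times.
    """
    obs = tensor.observed
    drug_obs = obs.sum(axis=1)
    cell_obs = obs.sum(axis=0)
    if np.any(drug_obs < 2):
        bad = tensor.drugs[int(np.argmin(drug_obs))]
        raise ValueError(f"drug {bad!r} observed in fewer than 2 cells")
    if np.any(cell_obs < 2):
        bad = tensor.cells[int(np.argmin(cell_obs))]
        raise ValueError(f"cell {bad!r} observed for fewer than 2 drugs")
    rng = np.random.default_rng(seed)
    n_pairs = int(obs.sum())
    for attempt in range(1, max_attempts + 1):
        folds = np.zeros(obs.shape, dtype=int)
        folds[obs] = rng.integers(1, n_folds + 1, size=n_pairs)
        if _fold_counts_ok(folds, obs, n_folds):
            return FoldAssignment(
                list(tensor.drugs), list(tensor.cells), folds,
                n_folds, seed, attempt, run_id,
            )
    # report the margins of the final rejected candidate to aid diagnosis
    worst_drug = (folds > 0).sum(axis=1).min()
    worst_cell = (folds > 0).sum(axis=0).min()
    raise RuntimeError(
        f"no valid fold assignment in {max_attempts} attempts "
        f"(min observed cells/drug={worst_drug}, drugs/cell={worst_cell})"
    )


# ---------------------------------------------------------------------------
# cross-validation runner
# ---------------------------------------------------------------------------

MethodFn = Callable[[ExpressionTensor, str, str], np.ndarray]


def _per_pair(fn: MethodFn):
    def run(train, pairs):
        preds, errs = {}, {}
        for pair in pairs:
            try:
                preds[pair] = fn(train, *pair)
            except ImputationError as exc:
                errs[pair] = str(exc)
        return preds, errs

    return run


def _method_runner(method: str | MethodFn, params: object | None):
    """Build a per-fold runner: (training tensor, fold pairs) -> (preds, errors).

    Built-in methods share expensive state across the pairs of a fold (NCF
    similarity matrices per target cell, a single FunkSVD fit).
    """
    if callable(method):
        return _per_pair(method)
    if method == "ta":
        return _per_pair(impute_tissue_agnostic)
    if method == "mom":
        return _per_pair(impute_mom)
    if method == "ncf":
        ncf_params = params or NCFParams()

        def run_ncf(train, pairs):
            R = reshape_tensor(train)
            sims_by_cell: dict[str, np.ndarray] = {}
            preds, errs = {}, {}
            for d, c in pairs:
                if c not in sims_by_cell:
                    sims_by_cell[c] = drug_similarity(R, ncf_params, exclude_cell=c)
                try:
                    preds[(d, c)] = impute_ncf(
                        R, d, c, ncf_params, similarities=sims_by_cell[c]
                    )
                except ImputationError as exc:
                    errs[(d, c)] = str(exc)
            return preds, errs

        return run_ncf
    if method == "svd":
        svd_params = params or SVDParams()

        def run_svd(train, pairs):
            model = funk_svd_fit(reshape_tensor(train), svd_params)
            return {
                (d, c): funk_svd_predict(model, d, c) for d, c in pairs
            }, {}

        return run_svd
    raise ValueError(f"unknown imputation method {method!r}")


def run_cross_validation(
    tensor: ExpressionTensor,
    method: str | MethodFn,
    fold_assignment: FoldAssignment,
    params: object | None = None,
) -> tuple[ExpressionTensor, pd.DataFrame]:
    """Impute every observed pair from the other folds' data.

    For each fold f, the method sees a training tensor in which every pair
    of fold f is unobserved (values removed, mask cleared), and must impute
    all of fold f's pairs.  The union over folds yields exactly one imputed
    profile per observed pair.  Failures are recorded in the provenance
    frame and the pair left unimputed.
    """
    imputed = ExpressionTensor.empty_like(tensor)
    records = []
    runner = _method_runner(method, params)
    for f in range(1, fold_assignment.n_folds + 1):
        pairs = fold_assignment.pairs_in_fold(f)
        if not pairs:
            continue
        train = tensor.mask_pairs(pairs)
        for d, c in pairs:  # taint guard: fold data must be absent
            assert not train.is_observed(d, c)
        predictions, errors = runner(train, pairs)
        for d, c in pairs:
            if (d, c) in predictions:
                profile = np.asarray(predictions[(d, c)], dtype=float)
                if profile.shape != (tensor.n_genes,) or not np.isfinite(profile).all():
                    msg = "method returned a non-finite or misshapen profile"
                    logger.warning("fold %d: pair (%s, %s): %s", f, d, c, msg)
                    records.append((d, c, f, "failed", msg))
                    continue
                i, j = imputed.drug_index(d), imputed.cell_index(c)
                imputed.values[i, j, :] = profile
                imputed.observed[i, j] = True
                records.append((d, c, f, "ok", ""))
            else:
                msg = errors.get((d, c), "no prediction returned")
                logger.warning("fold %d: pair (%s, %s) unimputed: %s", f, d, c, msg)
                records.append((d, c, f, "failed", msg))
    provenance = pd.DataFrame(
        records, columns=["drug", "cell", "fold", "status", "detail"]
    )
    return imputed, provenance


# ---------------------------------------------------------------------------
# weighted Spearman
# ---------------------------------------------------------------------------

def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    # rescale weights so extreme Gaussian tails cannot underflow the sums
    w = w / w.max()
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx == 0 and vy == 0:
        # both rankings are completely tied under the weights; by
        # construction the weighted rank vectors coincide
        return 1.0
    if vx == 0 or vy == 0:
        return 0.0
    denom = np.sqrt(vx) * np.sqrt(vy)  # avoids underflow of vx*vy
    return float(np.clip(cov / denom, -1.0, 1.0))


def weighted_spearman(
    true_scores: np.ndarray,
    imputed_scores: np.ndarray,
    epsilon: float = 0.01,
    polarity: str = "positive",
) -> float:
    """Head-weighted rank agreement of two aligned score vectors, in [-1, 1].

    Both vectors are ranked (1-based, average ranks on ties) with rank 1 at
    the head of the result list for the given polarity.  Each position is
    weighted by ``2 * phi(true_rank | 0, n * epsilon)`` — the weights are
    anchored to the true list's ranks — and the weighted Pearson
    correlation of the two rank vectors is returned.
    """
    t = np.asarray(true_scores, dtype=float)
    m = np.asarray(imputed_scores, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ValueError("score vectors must be 1-D and aligned")
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 results")
    sign = -1.0 if polarity == "positive" else 1.0
    r_true = stats.rankdata(sign * t)
    r_imp = stats.rankdata(sign * m)
    w = 2.0 * stats.norm.pdf(r_true, loc=0.0, scale=n * epsilon)
    if w.sum() == 0:  # total underflow guard for extreme n*epsilon
        w = np.ones(n)
    return _weighted_pearson(r_true, r_imp, w)


def score_connectivity_agreement(
    true_tensor: ExpressionTensor,
    imputed_tensor: ExpressionTensor,
    cell: str,
    polarity: str = "negative",
    k: int = 50,
    epsilon: float = 0.01,
    p: float = DEFAULT_WEIGHT_EXPONENT,
) -> tuple[pd.Series, float]:
    """Per-query WSpe between true and imputed connectivity rankings.

    For every drug observed in ``cell``: its signature is extracted from the
    *true* profile, all drugs are ranked by WCS against the true and against
    the imputed profiles, and the two rankings are compared with
    :func:`weighted_spearman`.  Returns the per-query series and its mean.
    """
    j = true_tensor.cell_index(cell)
    drugs = [
        d for i, d in enumerate(true_tensor.drugs) if true_tensor.observed[i, j]
    ]
    usable = [d for d in drugs if imputed_tensor.is_observed(d, cell)]
    skipped = sorted(set(drugs) - set(usable))
    if skipped:
        logger.warning(
            "cell %s: %d drugs lack an imputed profile and are skipped: %s",
            cell, len(skipped), skipped,
        )
    if len(usable) < 2:
        raise ValueError(f"cell {cell!r} has fewer than 2 comparable drugs")
    genes = true_tensor.genes
    ranked_true = {
        d: RankedProfile.from_scores(genes, true_tensor.profile(d, cell))
        for d in usable
    }
    ranked_imp = {
        d: RankedProfile.from_scores(genes, imputed_tensor.profile(d, cell))
        for d in usable
    }
    values = {}
    for d in usable:
        sig = extract_signature(genes, true_tensor.profile(d, cell), k)
        wcs_true = np.array(
            [_wcs_on_ranked(ranked_true[o], sig, p)[2] for o in usable]
        )
        wcs_imp = np.array(
            [_wcs_on_ranked(ranked_imp[o], sig, p)[2] for o in usable]
        )
        values[d] = weighted_spearman(
            wcs_true, wcs_imp, epsilon=epsilon, polarity=polarity
        )
    series = pd.Series(values, name="wspe")
    return series, float(series.mean())


def downsample(
    tensor: ExpressionTensor, cell: str, fraction: float, seed: int
) -> ExpressionTensor:
    """Randomly retain ``round(fraction * n_observed)`` drugs for one cell.

    Other cells are untouched.  ``fraction=1.0`` is an identity convenience.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return tensor.copy()
    j = tensor.cell_index(cell)
    observed_drugs = np.flatnonzero(tensor.observed[:, j])
    n_keep = round(fraction * observed_drugs.size)
    if n_keep < 2:
        raise ValueError(
            f"fraction {fraction} would leave {n_keep} < 2 drugs in {cell!r}"
        )
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(observed_drugs, size=n_keep, replace=False).tolist())
    drop = [i for i in observed_drugs if i not in keep]
    return tensor.mask_pairs((tensor.drugs[i], cell) for i in drop)
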