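"""Drug-set ("perturbagen class") enrichment with permutation p-values.

A connectivity result — drugs ranked from most to least positively
connected — is tested for over-representation of a drug class near its
head, using the same weighted-KS statistic as gene-set enrichment but with
drugs as list elements and connectivity scores as weights.  The observed
score is normalized against set-size-matched random placements
(sign-stratified mean scaling), and significance is the fraction of
permuted scores at least as strong as the observed one, with an add-one
correction so p is never exactly zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    DEFAULT_WEIGHT_EXPONENT,
    RankedProfile,
    _wcs_on_ranked,
    ks_enrichment_batch,
)
from .data_model import ExpressionTensor, PCLCatalog, extract_signature

__all__ = [
    "DrugSetEnrichmentResult",
    "drug_set_enrichment",
    "permutation_null_scores",
    "stratified_scale_against_null",
    "pcl_recovery_matrix",
]

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05
DEFAULT_PERMUTATIONS = 1000


@dataclass
class DrugSetEnrichmentResult:
    drug: str | None
    cell: str | None
    pcl: str
    es: float
    ncs: float
    p_value: float
    n_permutations: int
    n_members: int

    @property
    def significant(self) -> bool:
        return self.ncs > 0 and self.p_value < SIGNIFICANCE_LEVEL


def permutation_null_scores(
    ranked_scores: np.ndarray,
    set_size: int,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    p: float = DEFAULT_WEIGHT_EXPONENT,
    exhaustive: bool = False,
) -> np.ndarray:
    """Enrichment scores of random (or all) placements of a set in the list.

    Shuffling the drug labels of a ranked result while keeping the score
    vector fixed is equivalent to drawing the member positions uniformly
    without replacement, which is what happens here.  With
    ``exhaustive=True`` every C(n, m) placement is enumerated instead.
    """
    n = len(ranked_scores)
    if exhaustive:
        positions = np.array(
            list(itertools.combinations(range(n), set_size)), dtype=int
        )
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        positions = np.empty((n_permutations, set_size), dtype=int)
        for b in range(n_permutations):
            positions[b] = np.sort(rng.choice(n, size=set_size, replace=False))
    return ks_enrichment_batch(ranked_scores, positions, p=p)


def stratified_scale_against_null(
    es: np.ndarray | float, null_es: np.ndarray
) -> np.ndarray | float:
    """Mean-scale scores by the sign strata of the permutation null.

    Positive scores are divided by the mean positive null score, negative
    ones by the absolute mean negative null score.  If a stratum is empty
    (or all-zero) its scores map to zero.
    """
    scalar = np.isscalar(es) or np.ndim(es) == 0
    es = np.atleast_1d(np.asarray(es, dtype=float))
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    mu_pos = abs(pos.mean()) if pos.size else 0.0
    mu_neg = abs(neg.mean()) if neg.size else 0.0
    out = np.zeros_like(es)
    if mu_pos > 0:
        sel = es > 0
        out[sel] = es[sel] / mu_pos
    if mu_neg > 0:
        sel = es < 0
        out[sel] = es[sel] / mu_neg
    return float(out[0]) if scalar else out


def drug_set_enrichment(
    drugs: Sequence[str],
    scores: np.ndarray,
    pcl_members: Iterable[str],
    pcl: str = "",
    query_drug: str | None = None,
    cell: str | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    p: float = DEFAULT_WEIGHT_EXPONENT,
    exhaustive: bool = False,
) -> DrugSetEnrichmentResult:
    """Enrichment of a drug class within a connectivity result.

    ``drugs``/``scores`` are the connectivity result; the list is ranked by
    descending score internally (ties broken by drug identifier).  The query
    drug, if given, is removed from both the list and its own class.  The
    class must retain at least 2 members present in the list.

    The p-value follows the add-one permutation rule
    ``p = (1 + #{stronger nulls}) / (1 + B)`` where "stronger" means
    ``|NCS_perm| >= |NCS_obs|`` for non-negative observed scores and
    ``NCS_perm <= NCS_obs`` for negative ones.
    """
    drugs = [str(d) for d in drugs]
    members = {str(m) for m in pcl_members}
    if query_drug is not None:
        drugs_kept = [d for d in drugs if d != query_drug]
        keep = [i for i, d in enumerate(drugs) if d != query_drug]
        scores = np.asarray(scores, dtype=float)[keep]
        drugs = drugs_kept
        members.discard(query_drug)
    members &= set(drugs)
    if len(members) < 2:
        raise ValueError(
            f"PCL {pcl!r} has {len(members)} member(s) in the result after "
            "removing the query drug; need at least 2"
        )
    ranked = RankedProfile.from_scores(drugs, scores)
    positions = ranked.positions(members)
    es = float(ks_enrichment_batch(ranked.ranked_scores, positions[None, :], p=p)[0])
    null_es = permutation_null_scores(
        ranked.ranked_scores, len(members),
        n_permutations=n_permutations, seed=seed, p=p, exhaustive=exhaustive,
    )
    ncs = stratified_scale_against_null(es, null_es)
    null_ncs = stratified_scale_against_null(null_es, null_es)
    if ncs >= 0:
        stronger = int((np.abs(null_ncs) >= abs(ncs)).sum())
    else:
        stronger = int((null_ncs <= ncs).sum())
    b = len(null_es)
    p_value = (1 + stronger) / (1 + b)
    return DrugSetEnrichmentResult(
        drug=query_drug, cell=cell, pcl=pcl, es=es, ncs=float(ncs),
        p_value=p_value, n_permutations=b, n_members=len(members),
    )


def pcl_recovery_matrix(
    imputed_tensor: ExpressionTensor,
    true_tensor: ExpressionTensor,
    catalog: PCLCatalog,
    signature_k: int = 50,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    p: float = DEFAULT_WEIGHT_EXPONENT,
    query_target: str = "true",
    cells: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of drugs significantly enriched in their class, per (PCL, cell).

    For every drug in a usable class and every cell where its imputed
    profile exists: a signature is extracted from the *imputed* profile,
    ranked against the target matrix (``'true'`` or ``'imputed'``), and the
    drug counts as recovered iff its class NCS is positive with p < 0.05.

    Returns ``(per_drug, summary)`` frames; classes below the size floor are
    reported in the log and excluded.
    """
    if query_target not in ("true", "imputed"):
        raise ValueError("query_target must be 'true' or 'imputed'")
    target = true_tensor if query_target == "true" else imputed_tensor
    usable = catalog.usable_classes(true_tensor.drugs)
    dropped = sorted(set(catalog.classes) - set(usable))
    if dropped:
        logger.info(
            "excluding %d PCL(s) below the %d-member floor: %s",
            len(dropped), catalog.min_size, dropped,
        )
    cells = list(cells) if cells is not None else list(true_tensor.cells)
    genes = true_tensor.genes
    rows = []
    root = np.random.default_rng(seed)
    for cell in cells:
        j = target.cell_index(cell)
        pool = [
            d for i, d in enumerate(target.drugs) if target.observed[i, j]
        ]
        if len(pool) < 3:
            continue
        ranked_target = {
            d: RankedProfile.from_scores(genes, target.profile(d, cell))
            for d in pool
        }
        for pcl_name in sorted(usable):
            members = usable[pcl_name]
            for d in sorted(members):
                if not imputed_tensor.is_observed(d, cell):
                    continue
                sig = extract_signature(
                    genes, imputed_tensor.profile(d, cell), signature_k
                )
                others = [o for o in pool if o != d]
                wcs = np.array(
                    [_wcs_on_ranked(ranked_target[o], sig, p)[2] for o in others]
                )
                try:
                    res = drug_set_enrichment(
                        others, wcs, members, pcl=pcl_name, query_drug=d,
                        cell=cell, n_permutations=n_permutations,
                        seed=root.spawn(1)[0], p=p,
                    )
                except ValueError as exc:
                    logger.info("skipping %s/%s/%s: %s", d, cell, pcl_name, exc)
                    continue
                rows.append(
                    (pcl_name, cell, d, res.es, res.ncs, res.p_value,
                     res.significant)
                )
    per_drug = pd.DataFrame(
        rows, columns=["pcl", "cell", "drug", "es", "ncs", "p", "significant"]
    )
    if per_drug.empty:
        summary = pd.DataFrame(
            columns=["pcl", "cell", "pct_recovered", "n_drugs"]
        )
    else:
        summary = (
            per_drug.groupby(["pcl", "cell"], sort=True)
            .agg(
                pct_recovered=("significant", lambda s: 100.0 * s.mean()),
                n_drugs=("significant", "size"),
            )
            .reset_index()
        )
    return per_drug, summary
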