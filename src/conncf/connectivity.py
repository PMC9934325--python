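"""Weighted-KS enrichment, connectivity scores, and ranked queries.

The enrichment statistic walks a reference list ranked by descending
z-score.  Hits (members of the query gene set) advance the running sum by
``|z|^p`` normalized by the total hit weight; misses retreat it by
``1/(n_total - n_set)``.  The score is the signed maximum deviation of the
running sum and lies in [-1, 1].  With ``p = 0`` this reduces to the
classical two-sample Kolmogorov-Smirnov statistic.

A weighted connectivity score (WCS) combines the enrichment of the up and
down sets of a query signature: ``(ES_up - ES_down) / 2`` when the two have
opposite signs, and exactly 0 otherwise.  Normalized scores (NCS) rescale
the WCS by the absolute mean of same-sign scores within a normalization
group (one cell's result set for a single query).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionTensor, QuerySignature

__all__ = [
    "enrichment_score",
    "weighted_connectivity_score",
    "mean_scale",
    "normalize_scores",
    "query",
    "ConnectivityResult",
    "RankedProfile",
    "ks_enrichment_batch",
]

DEFAULT_WEIGHT_EXPONENT = 1.0


def ks_enrichment_batch(
    ranked_scores: np.ndarray,
    positions: np.ndarray,
    p: float = DEFAULT_WEIGHT_EXPONENT,
) -> np.ndarray:
    """Weighted-KS enrichment for one or more hit-position sets.

    Parameters
    ----------
    ranked_scores
        Scores of the reference list, already ordered by descending score,
        shape ``(n_total,)``.
    positions
        0-based hit positions, shape ``(n_batches, n_set)``; each row must be
        sorted ascending.
    p
        Weight exponent applied to ``|score|`` at hit positions.  If a row's
        total hit weight is zero the hits fall back to uniform weights.

    Returns
    -------
    Array of shape ``(n_batches,)`` with the signed maximum deviation of the
    running sum for each row; when the positive and negative extremes tie in
    magnitude the positive one is returned.
    """
    ranked_scores = np.asarray(ranked_scores, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=int))
    n_total = ranked_scores.shape[0]
    n_set = positions.shape[1]
    if n_set < 1:
        raise ValueError("gene set must be non-empty")
    if n_set >= n_total:
        raise ValueError(
            "gene set must be a proper subset of the ranked list "
            f"(set size {n_set} >= list size {n_total})"
        )
    w = np.abs(ranked_scores[positions]) ** p
    cw = np.cumsum(w, axis=1)
    total = cw[:, -1:]  # cumsum tail, so cum/total ends at exactly 1.0
    ordinal = np.arange(1, n_set + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.where(total > 0, cw / total, ordinal / n_set)
        cum_prev = np.where(total > 0, (cw - w) / total, (ordinal - 1) / n_set)
    miss = 1.0 / (n_total - n_set)
    # deviation immediately after each hit, and immediately before it
    after = cum - (positions + 1 - ordinal) * miss
    before = cum_prev - (positions - (ordinal - 1)) * miss
    max_dev = after.max(axis=1)
    min_dev = before.min(axis=1)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


@dataclass(eq=False)
class RankedProfile:
    """A profile ordered by descending score with O(1) position lookup.

    Ties in score are broken by ascending identifier so the ranking is
    deterministic across platforms.
    """

    ids: list[str]
    ranked_scores: np.ndarray
    _pos: dict[str, int] = field(repr=False, default_factory=dict)

    @classmethod
    def from_scores(cls, ids: Sequence[str], scores: np.ndarray) -> "RankedProfile":
        ids = [str(i) for i in ids]
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(ids),):
            raise ValueError("scores length does not match identifier list")
        if len(set(ids)) != len(ids):
            raise ValueError("ranked profile has duplicate identifiers")
        if not np.isfinite(scores).all():
            raise ValueError("ranked profile has non-finite scores")
        key = np.empty(len(ids), dtype=int)
        key[np.argsort(np.asarray(ids, dtype=object))] = np.arange(len(ids))
        order = np.lexsort((key, -scores))
        ranked_ids = [ids[i] for i in order]
        obj = cls(ranked_ids, scores[order])
        obj._pos = {g: r for r, g in enumerate(ranked_ids)}
        return obj

    def positions(self, members: Iterable[str]) -> np.ndarray:
        missing = [m for m in members if m not in self._pos]
        if missing:
            raise ValueError(f"identifiers absent from profile: {sorted(missing)}")
        return np.sort(np.fromiter((self._pos[m] for m in members), dtype=int))

    def enrichment(self, members: Iterable[str], p: float = DEFAULT_WEIGHT_EXPONENT) -> float:
        pos = self.positions(members)
        return float(ks_enrichment_batch(self.ranked_scores, pos[None, :], p=p)[0])


def enrichment_score(
    genes: Sequence[str],
    scores: np.ndarray,
    gene_set: Iterable[str],
    p: float = DEFAULT_WEIGHT_EXPONENT,
) -> float:
    """Weighted-KS enrichment of ``gene_set`` in the profile, in [-1, 1]."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    if len(gene_set) >= len(genes):
        raise ValueError("gene set must be smaller than the gene universe")
    return RankedProfile.from_scores(genes, scores).enrichment(gene_set, p=p)


def weighted_connectivity_score(
    genes: Sequence[str],
    scores: np.ndarray,
    signature: QuerySignature,
    p: float = DEFAULT_WEIGHT_EXPONENT,
) -> tuple[float, float, float]:
    """Return ``(ES_up, ES_down, WCS)`` for one profile and one signature.

    WCS is ``(ES_up - ES_down) / 2`` when the signs differ and 0 otherwise.
    """
    ranked = RankedProfile.from_scores(genes, scores)
    return _wcs_on_ranked(ranked, signature, p)


def _wcs_on_ranked(
    ranked: RankedProfile, signature: QuerySignature, p: float
) -> tuple[float, float, float]:
    es_up = ranked.enrichment(signature.up, p=p)
    es_down = ranked.enrichment(signature.down, p=p)
    if np.sign(es_up) != np.sign(es_down):
        wcs = (es_up - es_down) / 2.0
    else:
        wcs = 0.0
    return es_up, es_down, wcs


def mean_scale(wcs: np.ndarray) -> np.ndarray:
    """Sign-stratified mean scaling of one normalization group.

    Positive scores are divided by the mean of the positive scores,
    negative scores by the absolute mean of the negative scores; zeros stay
    zero.  A stratum whose mean is zero (possible only if every score in it
    is zero) maps to zero.
    """
    wcs = np.asarray(wcs, dtype=float)
    ncs = np.zeros_like(wcs)
    pos = wcs > 0
    neg = wcs < 0
    if pos.any():
        mu = abs(wcs[pos].mean())
        if mu > 0:
            ncs[pos] = wcs[pos] / mu
    if neg.any():
        mu = abs(wcs[neg].mean())
        if mu > 0:
            ncs[neg] = wcs[neg] / mu
    return ncs


def normalize_scores(records: pd.DataFrame | Iterable[tuple]) -> pd.DataFrame:
    """Add an ``ncs`` column to (cell, drug, wcs) records, grouping by cell."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["cell", "drug", "wcs"])
    out = records.copy()
    out["ncs"] = 0.0
    for _, idx in out.groupby("cell").groups.items():
        out.loc[idx, "ncs"] = mean_scale(out.loc[idx, "wcs"].to_numpy())
    return out


@dataclass(eq=False)
class ConnectivityResult:
    """Per-drug connectivity of one query against one cell's profiles."""

    cell: str
    query: QuerySignature
    polarity: str
    drugs: list[str]
    es_up: np.ndarray
    es_down: np.ndarray
    wcs: np.ndarray
    ncs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drugs,
                "es_up": self.es_up,
                "es_down": self.es_down,
                "wcs": self.wcs,
                "ncs": self.ncs,
                "rank": np.arange(1, len(self.drugs) + 1),
            }
        )


def query(
    tensor: ExpressionTensor,
    cell: str,
    signature: QuerySignature,
    polarity: str = "positive",
    p: float = DEFAULT_WEIGHT_EXPONENT,
) -> ConnectivityResult:
    """Rank every drug observed in ``cell`` by its WCS against ``signature``.

    ``polarity='positive'`` sorts descending (mimickers first);
    ``'negative'`` sorts ascending (reversers first).  Ties are broken by
    drug identifier.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    missing = (set(signature.up) | set(signature.down)) - set(tensor.genes)
    if missing:
        raise ValueError(
            f"signature genes absent from tensor gene axis: {sorted(missing)}"
        )
    j = tensor.cell_index(cell)
    drugs = [d for i, d in enumerate(tensor.drugs) if tensor.observed[i, j]]
    if not drugs:
        raise ValueError(f"cell {cell!r} has no observed profiles")
    rows = []
    for d in drugs:
        ranked = RankedProfile.from_scores(tensor.genes, tensor.profile(d, cell))
        rows.append(_wcs_on_ranked(ranked, signature, p))
    es_up, es_down, wcs = (np.array(col) for col in zip(*rows))
    ncs = mean_scale(wcs)
    sign = -1.0 if polarity == "positive" else 1.0
    key = np.empty(len(drugs), dtype=int)
    key[np.argsort(np.asarray(drugs, dtype=object))] = np.arange(len(drugs))
    order = np.lexsort((key, sign * wcs))
    return ConnectivityResult(
        cell=cell,
        query=signature,
        polarity=polarity,
        drugs=[drugs[i] for i in order],
        es_up=es_up[order],
        es_down=es_down[order],
        wcs=wcs[order],
        ncs=ncs[order],
    )
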