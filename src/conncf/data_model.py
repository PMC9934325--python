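"""Core data structures and text I/O for drug x cell x gene z-score tensors.

The central object is :class:`ExpressionTensor`, a dense ``(drug, cell, gene)``
array of differential-expression z-scores with an all-or-nothing observation
mask per ``(drug, cell)`` pair: a pair either carries a z-score for every gene
or for none.  :class:`ReshapedMatrix` is the 2-D ``drugs x (cells*genes)``
view used by the collaborative-filtering imputers.

Supported on-disk formats are plain text only:

* long-format TSV with columns ``drug, cell, gene, zscore`` (missing pairs
  are simply absent);
* GCT 1.3 text with genes as rows and one column per observed pair, labelled
  ``<drug>:<cell>``.

Identifiers are opaque strings; no symbol mapping is performed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTensor",
    "ReshapedMatrix",
    "QuerySignature",
    "PCLCatalog",
    "CellAnnotation",
    "reshape_tensor",
    "extract_signature",
    "read_tensor",
    "write_tensor",
    "read_pcl_catalog",
    "write_pcl_catalog",
    "read_cell_annotation",
    "write_cell_annotation",
    "read_signature",
    "write_signature",
]

CELL_CATEGORIES = ("cancer", "immortalized", "stem", "primary")


def _check_unique(ids: Sequence[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {axis} identifier: {dup!r}")


@dataclass(eq=False)
class ExpressionTensor:
    """Dense z-score tensor with an all-or-nothing (drug, cell) mask.

    Parameters
    ----------
    drugs, cells, genes
        Ordered, unique identifiers for each axis.
    values
        Float array of shape ``(n_drugs, n_cells, n_genes)``.  Entries of
        unobserved pairs are normalized to NaN on construction; the
        ``observed`` mask, not the values, is authoritative.
    observed
        Boolean array of shape ``(n_drugs, n_cells)``.
    """

    drugs: list[str]
    cells: list[str]
    genes: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.drugs = [str(d) for d in self.drugs]
        self.cells = [str(c) for c in self.cells]
        self.genes = [str(g) for g in self.genes]
        self.values = np.array(self.values, dtype=float)
        self.observed = np.array(self.observed, dtype=bool)
        self.validate()
        # normalize: unobserved blocks carry NaN so they can never be read
        self.values[~self.observed, :] = np.nan
        self._di = {d: i for i, d in enumerate(self.drugs)}
        self._ci = {c: j for j, c in enumerate(self.cells)}
        self._gi = {g: k for k, g in enumerate(self.genes)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def drug_index(self, drug: str) -> int:
        try:
            return self._di[drug]
        except KeyError:
            raise KeyError(f"unknown drug {drug!r}") from None

    def cell_index(self, cell: str) -> int:
        try:
            return self._ci[cell]
        except KeyError:
            raise KeyError(f"unknown cell {cell!r}") from None

    def is_observed(self, drug: str, cell: str) -> bool:
        return bool(self.observed[self.drug_index(drug), self.cell_index(cell)])

    def profile(self, drug: str, cell: str) -> np.ndarray:
        """Return the per-gene z-score vector of an observed pair (a copy)."""
        i, j = self.drug_index(drug), self.cell_index(cell)
        if not self.observed[i, j]:
            raise ValueError(f"pair ({drug!r}, {cell!r}) is not observed")
        return self.values[i, j].copy()

    def observed_pairs(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(self.observed)
        return [(self.drugs[i], self.cells[j]) for i, j in zip(ii, jj)]

    # -- validation / manipulation ----------------------------------------
    def validate(self) -> None:
        _check_unique(self.drugs, "drug")
        _check_unique(self.cells, "cell")
        _check_unique(self.genes, "gene")
        shape = (len(self.drugs), len(self.cells), len(self.genes))
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != {shape}")
        if self.observed.shape != shape[:2]:
            raise ValueError(
                f"observed shape {self.observed.shape} != {shape[:2]}"
            )
        bad = self.observed & ~np.isfinite(self.values).all(axis=2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "all-or-nothing violation: observed pair "
                f"({self.drugs[i]!r}, {self.cells[j]!r}) has non-finite z-scores"
            )

    def copy(self) -> "ExpressionTensor":
        return ExpressionTensor(
            list(self.drugs), list(self.cells), list(self.genes),
            self.values.copy(), self.observed.copy(),
        )

    def mask_pairs(self, pairs: Iterable[tuple[str, str]]) -> "ExpressionTensor":
        """Return a copy with the given (drug, cell) pairs made unobserved."""
        out = self.copy()
        for d, c in pairs:
            i, j = out.drug_index(d), out.cell_index(c)
            out.observed[i, j] = False
            out.values[i, j, :] = np.nan
        return out

    def canonicalized(self) -> "ExpressionTensor":
        """A copy with all three axes sorted lexicographically.

        File formats that omit unobserved pairs can only preserve axis order
        up to first appearance; canonical forms compare content exactly.
        """
        di = np.argsort(np.asarray(self.drugs, dtype=object))
        ci = np.argsort(np.asarray(self.cells, dtype=object))
        gi = np.argsort(np.asarray(self.genes, dtype=object))
        return ExpressionTensor(
            [self.drugs[i] for i in di],
            [self.cells[j] for j in ci],
            [self.genes[k] for k in gi],
            self.values[np.ix_(di, ci, gi)],
            self.observed[np.ix_(di, ci)],
        )

    def equals(self, other: "ExpressionTensor") -> bool:
        return (
            self.drugs == other.drugs
            and self.cells == other.cells
            and self.genes == other.genes
            and np.array_equal(self.observed, other.observed)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    @classmethod
    def empty_like(cls, other: "ExpressionTensor") -> "ExpressionTensor":
        """A tensor with the same axes and no observed pairs."""
        shape = (other.n_drugs, other.n_cells, other.n_genes)
        return cls(
            list(other.drugs), list(other.cells), list(other.genes),
            np.full(shape, np.nan), np.zeros(shape[:2], dtype=bool),
        )


@dataclass(eq=False)
class ReshapedMatrix:
    """2-D ``drugs x (cells*genes)`` view of an :class:`ExpressionTensor`.

    Columns are cell-major: all genes of the first cell, then all genes of
    the second cell, and so on.  Missingness is carried by the explicit
    per-(drug, cell) ``observed`` mask — never by a sentinel value — so 0.0
    remains a legal z-score.  Entries of unobserved blocks hold NaN purely
    as a guard against accidental reads.
    """

    drugs: list[str]
    cells: list[str]
    genes: list[str]
    values: np.ndarray  # (n_drugs, n_cells * n_genes)
    observed: np.ndarray  # (n_drugs, n_cells)

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        self.observed = np.array(self.observed, dtype=bool)
        d, c, g = len(self.drugs), len(self.cells), len(self.genes)
        if self.values.shape != (d, c * g):
            raise ValueError("reshaped values have wrong shape")
        if self.observed.shape != (d, c):
            raise ValueError("observed mask has wrong shape")
        self._di = {dr: i for i, dr in enumerate(self.drugs)}
        self._ci = {ce: j for j, ce in enumerate(self.cells)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def column_block(self, cell: str | int) -> slice:
        j = cell if isinstance(cell, int) else self._ci[cell]
        g = self.n_genes
        return slice(j * g, (j + 1) * g)

    def column_mask(self) -> np.ndarray:
        """Per-entry observation mask, shape ``(n_drugs, n_cells*n_genes)``."""
        return np.repeat(self.observed, self.n_genes, axis=1)

    @property
    def columns(self) -> list[tuple[str, str]]:
        return [(c, g) for c in self.cells for g in self.genes]

    def to_tensor(self) -> ExpressionTensor:
        d, c, g = len(self.drugs), len(self.cells), len(self.genes)
        return ExpressionTensor(
            list(self.drugs), list(self.cells), list(self.genes),
            self.values.reshape(d, c, g).copy(), self.observed.copy(),
        )


def reshape_tensor(tensor: ExpressionTensor) -> ReshapedMatrix:
    """Flatten a tensor into its drugs x (cells*genes) matrix view.

    The inverse, :meth:`ReshapedMatrix.to_tensor`, reconstructs the tensor
    bit-exactly.
    """
    d, c, g = tensor.n_drugs, tensor.n_cells, tensor.n_genes
    return ReshapedMatrix(
        list(tensor.drugs), list(tensor.cells), list(tensor.genes),
        tensor.values.reshape(d, c * g).copy(), tensor.observed.copy(),
    )


@dataclass(frozen=True)
class QuerySignature:
    """Up/down gene sets of a connectivity query (k genes per side)."""

    up: frozenset[str]
    down: frozenset[str]
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not self.up or not self.down:
            raise ValueError("up and down sets must be non-empty")
        if len(self.up) > self.k or len(self.down) > self.k:
            raise ValueError("signature side larger than k")

    def flipped(self) -> "QuerySignature":
        return QuerySignature(self.down, self.up, self.k)


def extract_signature(
    genes: Sequence[str], profile: np.ndarray, k: int
) -> QuerySignature:
    """Top-k / bottom-k gene sets of a per-gene z-score vector.

    Ties at either boundary are broken deterministically: among equal
    z-scores the lexicographically smaller identifier wins the last slot.
    In the fully degenerate case where a gene qualifies for both extremes
    (possible only under massive ties), the up set is filled first and the
    down set drawn from the remaining genes.
    """
    genes = [str(g) for g in genes]
    z = np.asarray(profile, dtype=float)
    if z.shape != (len(genes),):
        raise ValueError("profile length does not match gene list")
    if k < 1:
        raise ValueError("k must be >= 1")
    finite = np.flatnonzero(np.isfinite(z))
    if finite.size < 2 * k:
        raise ValueError(
            f"need at least {2 * k} finite z-scores, got {finite.size}"
        )
    # rank of each gene identifier in lexicographic order, for tie-breaking
    key = np.empty(len(genes), dtype=int)
    key[np.argsort(np.asarray(genes, dtype=object))] = np.arange(len(genes))
    up_order = finite[np.lexsort((key[finite], -z[finite]))]
    up = [genes[i] for i in up_order[:k]]
    up_set = set(up)
    down_order = finite[np.lexsort((key[finite], z[finite]))]
    down = [genes[i] for i in down_order if genes[i] not in up_set][:k]
    return QuerySignature(frozenset(up), frozenset(down), k)


@dataclass
class PCLCatalog:
    """Perturbagen-class membership: class name -> set of drug identifiers."""

    classes: dict[str, set[str]]
    min_size: int = 3

    def usable_classes(self, drugs: Iterable[str]) -> dict[str, set[str]]:
        """Classes with at least ``min_size`` members present among ``drugs``."""
        pool = set(drugs)
        return {
            name: members & pool
            for name, members in self.classes.items()
            if len(members & pool) >= self.min_size
        }

    def class_of(self, drug: str) -> list[str]:
        return sorted(n for n, m in self.classes.items() if drug in m)


@dataclass
class CellAnnotation:
    """Cell identifier -> category in {cancer, immortalized, stem, primary}."""

    categories: dict[str, str]

    def __post_init__(self) -> None:
        for cell, cat in self.categories.items():
            if cat not in CELL_CATEGORIES:
                raise ValueError(
                    f"cell {cell!r} has unknown category {cat!r}; "
                    f"expected one of {CELL_CATEGORIES}"
                )

    def validate_against(self, tensor: ExpressionTensor) -> None:
        missing = set(self.categories) - set(tensor.cells)
        if missing:
            raise ValueError(
                f"annotated cells absent from tensor: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return repr(float(v))


def infer_format(path: str | os.PathLike) -> str:
    return "gct" if str(path).lower().endswith(".gct") else "long-tsv"


def write_tensor(
    tensor: ExpressionTensor, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a tensor as long-format TSV or GCT 1.3 text.

    Floats are written with ``repr`` so every value round-trips exactly.
    """
    fmt = format or infer_format(path)
    if fmt in ("long-tsv", "long-TSV", "tsv"):
        _write_long_tsv(tensor, path)
    elif fmt == "gct":
        _write_gct(tensor, path)
    else:
        raise ValueError(f"unknown tensor format {fmt!r}")


def read_tensor(
    path: str | os.PathLike, format: str | None = None
) -> ExpressionTensor:
    fmt = format or infer_format(path)
    if fmt in ("long-tsv", "long-TSV", "tsv"):
        return _read_long_tsv(path)
    if fmt == "gct":
        return _read_gct(path)
    raise ValueError(f"unknown tensor format {fmt!r}")


def _write_long_tsv(tensor: ExpressionTensor, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tcell\tgene\tzscore\n")
        for i, d in enumerate(tensor.drugs):
            for j, c in enumerate(tensor.cells):
                if not tensor.observed[i, j]:
                    continue
                for k, g in enumerate(tensor.genes):
                    fh.write(f"{d}\t{c}\t{g}\t{_fmt(tensor.values[i, j, k])}\n")


def _read_long_tsv(path: str | os.PathLike) -> ExpressionTensor:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"drug": str, "cell": str, "gene": str, "zscore": float},
        float_precision="round_trip",
    )
    required = ["drug", "cell", "gene", "zscore"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"long-TSV must have columns {required}")
    dup = df.duplicated(["drug", "cell", "gene"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (drug, cell, gene) row: ({row.drug!r}, {row.cell!r}, "
            f"{row.gene!r})"
        )
    drugs = list(dict.fromkeys(df["drug"]))
    cells = list(dict.fromkeys(df["cell"]))
    genes = list(dict.fromkeys(df["gene"]))
    gi = {g: k for k, g in enumerate(genes)}
    values = np.full((len(drugs), len(cells), len(genes)), np.nan)
    observed = np.zeros((len(drugs), len(cells)), dtype=bool)
    di = {d: i for i, d in enumerate(drugs)}
    ci = {c: j for j, c in enumerate(cells)}
    for (d, c), grp in df.groupby(["drug", "cell"], sort=False):
        if len(grp) != len(genes) or set(grp["gene"]) != set(genes):
            raise ValueError(
                f"all-or-nothing violation in pair ({d!r}, {c!r}): "
                f"{len(grp)} of {len(genes)} genes present"
            )
        i, j = di[d], ci[c]
        values[i, j, [gi[g] for g in grp["gene"]]] = grp["zscore"].to_numpy()
        observed[i, j] = True
    return ExpressionTensor(drugs, cells, genes, values, observed)


def _write_gct(tensor: ExpressionTensor, path: str | os.PathLike) -> None:
    bad = [d for d in tensor.drugs if ":" in d] + [c for c in tensor.cells if ":" in c]
    if bad:
        raise ValueError(
            f"identifiers may not contain ':' in GCT column labels: {bad}"
        )
    pairs = tensor.observed_pairs()
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{tensor.n_genes}\t{len(pairs)}\t0\t0\n")
        fh.write("id\t" + "\t".join(f"{d}:{c}" for d, c in pairs) + "\n")
        cols = [
            (tensor.drug_index(d), tensor.cell_index(c)) for d, c in pairs
        ]
        for k, g in enumerate(tensor.genes):
            row = "\t".join(_fmt(tensor.values[i, j, k]) for i, j in cols)
            fh.write(f"{g}\t{row}\n")


def _read_gct(path: str | os.PathLike) -> ExpressionTensor:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.3", "#1.2"):
            raise ValueError(f"not a GCT text file (header {version!r})")
        dims = fh.readline().split("\t")
        n_genes, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(
            fh, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
    if df.shape != (n_genes, n_cols):
        raise ValueError(
            f"GCT dimension line says {(n_genes, n_cols)}, found {df.shape}"
        )
    pairs: list[tuple[str, str]] = []
    for col in df.columns:
        if ":" not in col:
            raise ValueError(f"GCT column {col!r} is not '<drug>:<cell>'")
        d, c = col.split(":", 1)
        pairs.append((d, c))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (drug, cell) columns in GCT")
    drugs = list(dict.fromkeys(d for d, _ in pairs))
    cells = list(dict.fromkeys(c for _, c in pairs))
    genes = [str(g) for g in df.index]
    raw = df.to_numpy(dtype=str)
    raw = np.where(np.isin(raw, ("NA", "NaN", "nan", "")), "nan", raw)
    mat = raw.astype(np.float64)  # numpy strtod round-trips repr exactly
    values = np.full((len(drugs), len(cells), len(genes)), np.nan)
    observed = np.zeros((len(drugs), len(cells)), dtype=bool)
    di = {d: i for i, d in enumerate(drugs)}
    ci = {c: j for j, c in enumerate(cells)}
    for col_idx, (d, c) in enumerate(pairs):
        column = mat[:, col_idx]
        finite = np.isfinite(column)
        if not finite.any():
            continue  # fully-NA column: pair treated as unobserved
        if not finite.all():
            raise ValueError(
                f"all-or-nothing violation in GCT column {d}:{c}: "
                f"{int((~finite).sum())} NA values"
            )
        values[di[d], ci[c], :] = column
        observed[di[d], ci[c]] = True
    return ExpressionTensor(drugs, cells, genes, values, observed)


def read_pcl_catalog(path: str | os.PathLike, min_size: int = 3) -> PCLCatalog:
    """Read a drug -> class TSV (columns ``drug``, ``class``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["drug", "class"]:
        raise ValueError("PCL TSV must have columns ['drug', 'class']")
    classes: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        classes.setdefault(row["class"], set()).add(row["drug"])
    return PCLCatalog(classes, min_size=min_size)


def write_pcl_catalog(catalog: PCLCatalog, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tclass\n")
        for name in sorted(catalog.classes):
            for drug in sorted(catalog.classes[name]):
                fh.write(f"{drug}\t{name}\n")


def read_cell_annotation(path: str | os.PathLike) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cell", "category"]:
        raise ValueError("cell annotation TSV must have columns ['cell', 'category']")
    return CellAnnotation(dict(zip(df["cell"], df["category"])))


def write_cell_annotation(ann: CellAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("cell\tcategory\n")
        for cell in sorted(ann.categories):
            fh.write(f"{cell}\t{ann.categories[cell]}\n")


def read_signature(path: str | os.PathLike) -> QuerySignature:
    """Read a signature TSV with columns ``gene``, ``direction`` (up|down)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "direction"]:
        raise ValueError("signature TSV must have columns ['gene', 'direction']")
    up = set(df.loc[df["direction"] == "up", "gene"])
    down = set(df.loc[df["direction"] == "down", "gene"])
    other = set(df["direction"]) - {"up", "down"}
    if other:
        raise ValueError(f"unknown signature direction(s): {sorted(other)}")
    return QuerySignature(frozenset(up), frozenset(down), max(len(up), len(down)))


def write_signature(sig: QuerySignature, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection\n")
        for g in sorted(sig.up):
            fh.write(f"{g}\tup\n")
        for g in sorted(sig.down):
            fh.write(f"{g}\tdown\n")
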