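"""Synthetic drug x cell x gene tensors with known ground truth.

The signal model layers a shared per-class gene signature, a cell-type
specific modulation of that signature (a gene-wise perturbation per
(class, cell type) plus a scalar responsiveness per cell type), an
additive per-cell offset, a drug-by-cell idiosyncrasy term, and i.i.d.
noise:

    z(d, c, g) = [class_sig(pcl(d), g) + delta(pcl(d), type(c), g)]
                 * resp(type(c))
                 + cell_offset(c, g) + interaction(d, c, g) + noise

``delta``, the deviation of ``resp`` from 1, and ``cell_offset`` all scale
with ``cell_modulation_sd``, so that single knob moves the data between the
"cell matters" and "cell doesn't matter" regimes.  The gene-wise ``delta``
term is what makes per-cell connectivity rankings genuinely cell-dependent
yet predictable from same-cell neighbors: a scalar responsiveness alone
rescales every class signature equally within a cell and leaves within-cell
rankings nearly invariant across cells.  Missingness is drawn per cell at a configurable assay
fraction, then topped up minimally so every drug is observed in at least
two cells (the evaluability requirement of the cross-validation harness).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    CELL_CATEGORIES,
    CellAnnotation,
    ExpressionTensor,
    PCLCatalog,
    write_cell_annotation,
    write_pcl_catalog,
    write_tensor,
)

__all__ = ["GeneratorConfig", "generate_dataset", "make_fixture", "FIXTURE_PRESETS"]


@dataclass
class GeneratorConfig:
    n_drugs: int = 40
    n_cells: int = 12
    n_genes: int = 100
    n_pcls: int = 6
    n_cell_types: int = 4
    class_effect_sd: float = 1.0
    cell_modulation_sd: float = 0.5
    interaction_sd: float = 0.1
    noise_sd: float = 0.1
    assay_fractions: list[float] | None = None  # None -> fully observed
    seed: int = 0
    pcl_size_range: tuple[int, int] = (3, 20)

    def __post_init__(self) -> None:
        for name in ("class_effect_sd", "cell_modulation_sd", "interaction_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pcls > self.n_drugs:
            raise ValueError("n_pcls cannot exceed n_drugs")
        if self.assay_fractions is not None:
            if len(self.assay_fractions) != self.n_cells:
                raise ValueError("need one assay fraction per cell")
            if any(not 0 <= f <= 1 for f in self.assay_fractions):
                raise ValueError("assay fractions must be in [0, 1]")


def _partition_drugs(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign drugs to classes with sizes ~ log-uniform in the given range."""
    lo, hi = config.pcl_size_range
    raw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_pcls))
    # largest-remainder apportionment of n_drugs to the drawn proportions
    quota = raw / raw.sum() * config.n_drugs
    sizes = np.floor(quota).astype(int)
    sizes = np.maximum(sizes, 1)
    while sizes.sum() > config.n_drugs:
        sizes[np.argmax(sizes)] -= 1
    rema = quota - np.floor(quota)
    while sizes.sum() < config.n_drugs:
        idx = int(np.argmax(rema))
        sizes[idx] += 1
        rema[idx] = -1
    labels = np.repeat(np.arange(config.n_pcls), sizes)
    rng.shuffle(labels)
    return labels


def _draw_mask(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    d, c = config.n_drugs, config.n_cells
    if config.assay_fractions is None:
        return np.ones((d, c), dtype=bool)
    if c < 2:
        raise ValueError("evaluability requires at least 2 cells")
    observed = np.zeros((d, c), dtype=bool)
    for j, frac in enumerate(config.assay_fractions):
        n_obs = round(frac * d)
        if n_obs < 2:
            raise ValueError(
                f"cell index {j}: assay fraction {frac} yields {n_obs} < 2 "
                "observed drugs (fold assignment would be impossible)"
            )
        observed[rng.choice(d, size=n_obs, replace=False), j] = True
    # top up drugs with < 2 observations by flipping random unobserved cells
    for i in range(d):
        deficit = 2 - int(observed[i].sum())
        if deficit > 0:
            free = np.flatnonzero(~observed[i])
            observed[i, rng.choice(free, size=deficit, replace=False)] = True
    return observed


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[ExpressionTensor, PCLCatalog, CellAnnotation, dict]:
    """Generate a tensor plus its PCL catalog, cell annotation, and truth.

    The truth dict carries every latent component (class signatures, cell
    responsiveness, offsets, class/type labels, the noiseless tensor) so
    oracle tests can check recovery directly.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    d, c, g = config.n_drugs, config.n_cells, config.n_genes
    drugs = [f"d{i:03d}" for i in range(d)]
    cells = [f"c{j:02d}" for j in range(c)]
    genes = [f"g{k:04d}" for k in range(g)]

    pcl_of_drug = _partition_drugs(config, rng)
    type_of_cell = np.arange(c) % config.n_cell_types  # even partition

    class_sig = rng.normal(0.0, config.class_effect_sd, size=(config.n_pcls, g))
    responsiveness = 1.0 + rng.normal(
        0.0, config.cell_modulation_sd, size=config.n_cell_types
    )
    type_modulation = rng.normal(
        0.0, config.cell_modulation_sd, size=(config.n_pcls, config.n_cell_types, g)
    )
    cell_offset = rng.normal(0.0, config.cell_modulation_sd, size=(c, g))
    interaction = rng.normal(0.0, config.interaction_sd, size=(d, c, g))
    noise = rng.normal(0.0, config.noise_sd, size=(d, c, g))

    modulated_sig = (
        class_sig[pcl_of_drug][:, None, :]
        + type_modulation[pcl_of_drug][np.arange(d)[:, None], type_of_cell, :]
    )
    signal = (
        modulated_sig * responsiveness[type_of_cell][None, :, None]
        + cell_offset[None, :, :]
    )
    values = signal + interaction + noise
    observed = _draw_mask(config, rng)
    values = np.where(observed[:, :, None], values, np.nan)
    tensor = ExpressionTensor(drugs, cells, genes, values, observed)

    classes: dict[str, set[str]] = {}
    for i, lbl in enumerate(pcl_of_drug):
        classes.setdefault(f"pcl{lbl:02d}", set()).add(drugs[i])
    catalog = PCLCatalog(classes, min_size=3)
    annotation = CellAnnotation(
        {
            cells[j]: CELL_CATEGORIES[type_of_cell[j] % len(CELL_CATEGORIES)]
            for j in range(c)
        }
    )
    truth = {
        "pcl_of_drug": pcl_of_drug,
        "type_of_cell": type_of_cell,
        "class_signatures": class_sig,
        "type_modulation": type_modulation,
        "responsiveness": responsiveness,
        "cell_offset": cell_offset,
        "interaction": interaction,
        "noise": noise,
        "noiseless": signal,
        "config": config,
    }
    return tensor, catalog, annotation, truth


def _sparse_like_fractions(n_cells: int) -> list[float]:
    # spread around 25% observed (~75% missing) with one under-5% cell
    fracs = 0.25 + 0.15 * np.linspace(-1.0, 1.0, n_cells)
    fracs[0] = 0.04
    return fracs.tolist()


FIXTURE_PRESETS: dict[str, GeneratorConfig] = {
    "tiny": GeneratorConfig(
        n_drugs=6, n_cells=4, n_genes=20, n_pcls=2, n_cell_types=2,
        assay_fractions=None,
    ),
    "complete_like": GeneratorConfig(
        n_drugs=40, n_cells=12, n_genes=100, n_pcls=6, n_cell_types=4,
        assay_fractions=None,
    ),
    "sparse_like": GeneratorConfig(
        n_drugs=120, n_cells=20, n_genes=100, n_pcls=12, n_cell_types=4,
        assay_fractions=_sparse_like_fractions(20),
    ),
}


def make_fixture(
    name: str, out_dir: str | os.PathLike, seed: int | None = None
) -> dict[str, Path]:
    """Write a named fixture (tensor in both formats, PCLs, annotations).

    Output is deterministic for a fixed seed, byte for byte.  Returns the
    paths keyed by role.
    """
    if name not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_PRESETS)}"
        )
    config = FIXTURE_PRESETS[name]
    if seed is not None:
        config = GeneratorConfig(**{**config.__dict__, "seed": seed})
    tensor, catalog, annotation, _ = generate_dataset(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tensor_tsv": out / f"{name}.tsv",
        "tensor_gct": out / f"{name}.gct",
        "pcl": out / f"{name}_pcls.tsv",
        "cells": out / f"{name}_cells.tsv",
    }
    write_tensor(tensor, paths["tensor_tsv"], "long-tsv")
    write_tensor(tensor, paths["tensor_gct"], "gct")
    write_pcl_catalog(catalog, paths["pcl"])
    write_cell_annotation(annotation, paths["cells"])
    return paths
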