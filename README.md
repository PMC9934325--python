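# conncf

Cell-specific imputation and connectivity scoring for drug × cell × gene
differential-expression z-score tensors.

Connectivity mapping ranks a library of drugs by how strongly each drug's
expression profile mimics (positive connectivity) or reverses (negative
connectivity) a query signature. When many (drug, cell) profiles are
unassayed, `conncf` imputes them and quantifies how faithfully connectivity
queries against imputed data reproduce queries against the real data.

## What's inside

- **`conncf.data_model`** — the `ExpressionTensor` (all-or-nothing
  missingness per (drug, cell) pair), its 2-D `drugs × (cells·genes)`
  reshaped view, query signatures (top-k/bottom-k gene sets), perturbagen
  class (PCL) catalogs, cell annotations, and text I/O (long-format TSV and
  GCT 1.3; PCL and annotation TSVs).
- **`conncf.connectivity`** — weighted Kolmogorov–Smirnov enrichment
  scores, weighted connectivity scores (WCS ∈ [−1, 1], zero when the up and
  down enrichments agree in sign), sign-stratified mean-scaled normalized
  scores (NCS), and ranked per-cell queries.
- **`conncf.imputation`** — four imputers for a withheld (drug, cell)
  profile: tissue-agnostic median (TA), median-of-medians (MoM),
  neighborhood collaborative filtering (NCF, adjusted-cosine similarity with
  target-cell columns excluded), and FunkSVD (SGD matrix factorization over
  observed entries only; numba-accelerated when available).
- **`conncf.evaluation`** — constrained five-fold cross-validation (no fold
  may hold more than 75% of a drug's cells or a cell's drugs; rejected
  assignments are regenerated whole), a leak-free CV runner, the
  head-weighted Spearman metric `w(r) = 2·φ(r | 0, n·ε)`, and per-cell
  drug downsampling.
- **`conncf.enrichment`** — drug-set ("PCL") enrichment of connectivity
  results with permutation p-values (add-one rule) and per-(PCL, cell)
  recovery summaries.
- **`conncf.synthetic`** — seeded generators for LINCS-like tensors with
  known ground truth: latent drug classes, cell-type-specific modulation,
  per-cell assay fractions, plus ready-made `tiny`, `complete_like`, and
  `sparse_like` fixtures.

## CLI

```sh
conncf simulate --preset sparse_like --seed 7 --out-dir fixtures/
conncf query --tensor X.tsv --signature sig.tsv --cell MCF7 \
       --polarity negative --out result.tsv
conncf impute --tensor X.tsv --method ncf --drug D --cell C --k 50 --out p.tsv
conncf xval --tensor X.tsv --method ncf --runs 5 --seed 7 --out-dir results/
conncf downsample --tensor X.tsv --cell PC3 --fraction 0.2 --out down.tsv
conncf enrich --imputed Ximp.tsv --true X.tsv --pcl pcls.tsv \
       --permutations 1000 --seed 7 --out enrich.tsv
```

Tensors are read as long-format TSV (`drug\tcell\tgene\tzscore`) or GCT 1.3
text (columns labelled `drug:cell`), chosen by file extension. Signature
TSVs have columns `gene\tdirection` (`up`/`down`).

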