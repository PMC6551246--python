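# scpowerkit

Empirical experimental design for single-cell RNA-seq cell-type
identification: how many cells must you profile, and which analysis
pipeline should you run, to detect a rare cell population?

`scpowerkit` answers these questions by simulation. It generates labeled
scRNA-seq count matrices with controlled cell-type rarity and marker-gene
fold change, runs pluggable cell-type-identification pipelines on them,
scores each pipeline against the known labels with the F1 score, and reads
off the smallest cell number at which a pipeline clears a user-chosen F1
threshold.

It is aimed at researchers planning a droplet scRNA-seq experiment who can
state their expectations in three numbers: the rarity of the population
they are after (e.g. 2–10% of cells), the fold change of its marker genes
over all other cells (e.g. insulin in beta cells is extreme; subtypes of a
known type may be only 2-fold), and candidate sequencing depths.

## Model

Counts follow a gamma–Poisson (negative binomial) hierarchy. For gene *i*
in a cell *j* of type *k* with library size *L<sub>j</sub>*:

- baseline gene means: *μ<sub>i</sub>* ~ Gamma(shape, rate)
- marker injection: each of *m* types upregulates *g* disjoint marker
  genes; for marker *i* of type *k*, *μ<sub>ik</sub>* = *f<sub>ik</sub>* ·
  *μ<sub>i</sub>* with fold-change factor *f<sub>ik</sub>* ~ Gamma(fC, 1)
  (mean fC; factors below 1 resampled by default so markers are strictly
  upregulated)
- library sizes: *L<sub>j</sub>* ~ LogNormal(location, scale)
- rates: *λ<sub>ij</sub>* = *μ<sub>ik</sub>* · *L<sub>j</sub>* / Σ<sub>i</sub>
  *μ<sub>ik</sub>*, multiplied by a unit-mean gamma variate with squared
  CV = `bcv_dispersion` (biological noise)
- counts: *c<sub>ij</sub>* ~ Poisson(*λ<sub>ij</sub>*), optionally thinned
  by logistic dropout (technical noise)

Three cell-type-identification backends ship behind a plugin registry, all
consuming one shared embedding (total-count normalization → log1p → top
highly-variable genes → scaling → PCA):

- `kmeans` — Lloyd k-means with k = number of types,
- `snn_louvain` — Seurat-style shared-nearest-neighbor graph + Louvain
  modularity, with a bounded resolution search toward the target cluster
  count,
- `mk_spectral` — SIMLR-style multi-kernel Gaussian similarity +
  normalized spectral clustering.

Scoring matches each predicted cluster to the true type holding the
plurality of its cells, pools TP/FP/FN per type, and reports per-type
precision, recall and F1 = 2PR/(P+R), plus the rare type's F1 (the
headline number for rare-population detection) and the macro mean.

## Worked example

Simulate 1000 cells in five types where the rarest is 5% of cells and its
50 markers are only 2-fold upregulated, cluster with the SNN-Louvain
backend, and score:

```python
from scpowerkit import (SimulationParams, generate_dataset, preprocess,
                        BackendSpec, run_backend, evaluate)

params = SimulationParams(n_cells=1000,
                          proportions=(0.05, 0.35, 0.2, 0.2, 0.2),
                          fold_change=2.0, seed=42)
ds = generate_dataset(params)               # 10,000 genes x 1000 cells
emb = preprocess(ds)                        # shared PCA embedding
assignment = run_backend(BackendSpec("snn_louvain"), emb, m_target=5, seed=42)
score = evaluate(ds.true_labels, assignment)
print(score.per_type.to_string(index=False))
print("rare_type_f1 =", round(score.rare_type_f1, 3),
      " macro_f1 =", round(score.macro_f1, 3))
```

prints

```
 type matched_clusters  true_count  precision  recall       f1
    1              [0]          50   1.000000    0.96 0.979592
    2              [2]         350   1.000000    1.00 1.000000
    3              [1]         200   0.990099    1.00 0.995025
    4              [3]         200   1.000000    1.00 1.000000
    5              [4]         200   1.000000    1.00 1.000000
rare_type_f1 = 0.98  macro_f1 = 0.995
```

Type 1 is the 50-cell rare population; the pipeline recovers 48 of its 50
cells in a pure cluster (recall 0.96, precision 1.0), so a 5%-rare type
with 2-fold markers is detectable at 1000 cells with this backend.

The factorial design — proportions × cell numbers × fold changes ×
backends × replicates — runs through `table1_grid()` / `run_grid()`, and
`min_cells_for_threshold(table, 0.9)` returns, per (backend, rarity, fold
change), the smallest tested cell number whose mean rare-type F1 reaches
0.9 (or the explicit value `"not achieved"`). `select_best_pipeline`
ranks backends for one scenario.

Everything is also available from the shell:

```
scpowerkit simulate --config sim.yaml --out ds/
scpowerkit cluster  --dataset ds/ --backend snn_louvain --seed 1 --out assign.tsv
scpowerkit evaluate --dataset ds/ --assignment assign.tsv --out scores.tsv
scpowerkit grid     --config grid.yaml --out run/
scpowerkit power    --table run/power_table.tsv --threshold 0.9 --out power.tsv
scpowerkit best     --table run/power_table.tsv --rarity 0.02 --fc 2 --n 1000
```

Datasets are written as portable MTX bundles (`counts.mtx`, `genes.tsv`,
`cells.tsv` with true labels, `markers.tsv`, `params.json`).

## Documentation

See `docs/methods.md` for the generative model's assumptions, parameter
defaults and their rationale, numerical choices, and known limitations.
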