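# Methods

## The design question

Detecting a rare cell population in an scRNA-seq experiment depends on
three design quantities: the population's prevalence (rarity), how strongly
its marker genes are upregulated (fold change, fC), and how many cells are
profiled (n). `scpowerkit` treats the question empirically: simulate data
with known labels across a factorial grid of these quantities, run
candidate analysis pipelines, and score them with the F1 of the rare type.
No analytic power formula is attempted — the answer is read off the grid
at discrete n levels.

## Generative model

A minimal splat-style gamma–Poisson hierarchy, chosen to capture the
statistical structure the benchmark needs (overdispersed counts, skewed
gene means, variable sequencing depth, group-specific marker shifts)
without the full feature set of heavier simulators (no batch effects,
trajectories, doublets, expression outliers or mean-trended dispersion).

Per dataset with m types, G genes, n cells:

1. **Cell allocation.** n cells are apportioned to the m types by
   largest-remainder rounding of n·proportions (ties to the lower type
   index). This is deterministic — the stated proportions are design
   targets, not sampling probabilities — so group sizes are exactly
   reproducible and a multinomial draw cannot accidentally empty the rare
   type. A design whose rarest type would receive zero cells is an error.
2. **Baseline means.** μ_i ~ Gamma(shape=0.6, rate=0.3) i.i.d. The gamma
   family gives the right-skewed mean distribution typical of expression
   data; shape < 1 puts substantial mass near zero (many near-silent
   genes), and mean shape/rate = 2 yields realistic relative abundances
   once normalized to the library size.
3. **Marker injection.** Each type k receives g disjoint marker genes
   (sampled uniformly without replacement from the dataset RNG). For
   marker i of type k, the type-k mean is f_ik · μ_i with
   f_ik ~ Gamma(shape=fC, rate=1), one draw per (marker, type). This
   distribution has mean exactly fC, so the nominal fold change is the
   expected group-vs-rest expression ratio (non-group cells are
   unperturbed for that gene). Because a Gamma(fC, 1) draw can fall below
   1, a truncation mode (default on) resamples sub-1 factors — markers are
   then strictly upregulated, matching the usual reading of "fC-fold
   upregulated markers". Truncation raises the realized mean above fC
   (e.g. ≈2.5 at fC = 2); the untruncated mode keeps the mean exactly fC
   and is what the fold-change calibration test uses.
4. **Library sizes.** L_j ~ LogNormal(location=ln 20,000, scale=0.2):
   median 20,000 total counts per cell with ~20% spread, a typical
   droplet-experiment depth.
5. **Counts.** λ_ij = μ_ik · L_j / Σ_i μ_ik — each type's mean profile is
   renormalized per cell so E[column sum] = L_j. Biological noise
   multiplies λ_ij by a unit-mean gamma variate with squared coefficient
   of variation `bcv_dispersion` (default 0.1); counts are
   Poisson(λ'_ij), giving Var = λ + bcv·λ² marginally. Optional logistic
   dropout zeroes an entry with probability
   sigmoid(shape·(midpoint − log λ)), decreasing in expression; it is off
   by default because the benchmark scenarios do not invoke it.

**RNG discipline.** One master seed spawns five named substreams (means,
markers, fold-changes, library sizes, counts) via `SeedSequence.spawn`, so
a dataset is a pure function of its parameters and adding a downstream
step can never perturb upstream draws. Two calls with equal parameters are
bit-identical.

### Defaults

| parameter | default | meaning |
|---|---|---|
| n_genes | 10,000 | genes per dataset |
| proportions | (0.1, 0.2, 0.2, 0.2, 0.3) | five types, 10% rare |
| n_markers_per_type | 50 | markers upregulated per type |
| fold_change | 2 | mean marker fold change (hardest benchmark level) |
| mean_shape, mean_rate | 0.6, 0.3 | gamma of baseline gene means |
| libsize_location, libsize_scale | ln 20,000, 0.2 | log-normal depth |
| bcv_dispersion | 0.1 | squared biological CV (0 → pure Poisson) |
| dropout | off | logistic technical zero-inflation |
| truncate_fc_below_one | on | resample factors < 1 |

The benchmark grid (`table1_grid`) crosses rarities {0.1, 0.05, 0.02}
(via three five-type proportion vectors), n ∈ {1000, 2000, 3000} and
fC ∈ {2, 4, 8} — 27 design cells — with 5 replicates by default.
Replicates stabilize the rare-type F1, which at rarity 0.02 rests on only
20–60 cells; a single-replicate mode reproduces a one-dataset-per-cell
protocol.

## Shared preprocessing

All backends cluster the same embedding so comparisons isolate the
clustering step: total-count normalization to 10,000 per cell, log1p, top
500 highly-variable genes (dispersion-based), per-gene scaling (clipped at
10 SD), PCA to 50 components (ARPACK, fixed random state; capped at
n_cells − 1 and at the HVG count). The HVG default is deliberately tight:
with 10,000 simulated genes of which m·g = 250 carry signal, a loose cut
admits thousands of noise-variable genes whose variance drowns the rare
type's direction in the PCA — at 2,000 HVGs a 2% subpopulation with 2-fold
markers is essentially invisible (10-NN purity of the rare cells ≈ 0.3),
at 500 it is recoverable (purity ≈ 0.7–0.95). Real data with stronger
markers or fewer genes tolerates looser cuts; the knob is exposed.

## Backends

All are deterministic given (input, settings, seed) and invariant to cell
order up to cluster relabeling; a registry lets users plug in any callable
with the (embedding, settings, seed) → assignment contract (e.g. to wrap
an external R pipeline).

- **kmeans.** Lloyd iterations, 10 restarts ranked by inertia (then
  restart index), k set to the number of simulated types.
- **snn_louvain** (Seurat-analog). k-nearest-neighbor graph on the
  embedding with k = `k_param` (neighbor sets include the cell itself),
  converted to a shared-nearest-neighbor graph weighted by Jaccard overlap
  of neighbor sets, edges below 1/15 pruned; Louvain modularity
  optimization. Louvain takes no cluster count, so when the found count
  differs from the target the resolution parameter is searched — geometric
  bracketing then bisection, at most 20 community runs — and the closest
  result is returned with the realized count recorded in the settings.
  For benchmark fidelity `k_param` defaults to the number of cell types
  (an unusually small neighbor count; standard practice is ~20) — the
  reproduced protocol sets it so, and it is exposed as a parameter.
- **mk_spectral** (SIMLR-analog). A bank of Gaussian kernels over
  Euclidean cell–cell distances: global bandwidths {0.5, 1, 2} × median
  pairwise distance plus local bandwidths from mean distances to the
  nearest 5% and 10% of cells. Kernels are averaged (uniform weights — the
  original method's kernel-weight learning is out of scope) and
  symmetrized, and the similarity is restricted to a symmetric kNN mask of
  1% of cells (floor 10). The mask plays the sparsifying role that
  similarity learning plays in the original: without it the dense
  similarity between large types dominates the graph's leading
  eigenvectors and a 2% block never surfaces. Normalized spectral
  clustering follows: top m eigenvectors of D^{-1/2} K D^{-1/2} (ARPACK
  with a fixed start vector; each eigenvector's sign fixed so its
  largest-magnitude entry is positive), rows normalized to the unit
  sphere, k-means with 10 restarts.

## Scoring

Predicted clusters carry arbitrary ids, so the m × C contingency table is
matched first: each cluster is assigned to the type holding the plurality
of its cells (ties to the lower type index; many-to-one allowed, which
handles Louvain's variable cluster counts gracefully). Per type, TP/FP/FN
are pooled over its matched clusters; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), and every zero-denominator case is
defined as 0, never NaN. A Hungarian one-to-one matching is available
behind a flag for sensitivity analysis. Two summaries are always reported:
the rare type's F1 (the type with the fewest true cells; the headline
number, since rare-population detection is the point) and the unweighted
macro mean. Plurality matching is not guaranteed to maximize macro F1 over
all many-to-one matchings, but it is the natural "annotate each cluster by
its dominant type" rule; the test suite compares it against an independent
brute-force implementation for exactness, not optimality.

## Grid running and power answers

Per grid cell and replicate, the dataset seed derives from the master seed
and the cell coordinates via SHA-256 (platform-stable, < 2³¹), so re-runs
reproduce the power table bit-for-bit while replicates differ. Each
dataset is simulated and embedded once; every backend clusters the shared
embedding. One backend failing on one dataset is logged and recorded as a
missing row rather than aborting the run (an abort flag exists); an
optional on-disk ledger appends completed rows and makes long grids
resumable. `min_cells_for_threshold` scans n levels in increasing order
and returns the first whose aggregated (mean or median) F1 clears the
threshold, with "not achieved" as an explicit value; it is monotone in the
threshold. `select_best_pipeline` ranks backends by aggregated rare-type
F1, ties broken by macro F1 then name.

## Problem sizes in the shipped tests

Unit tests run on scaled-down datasets (hundreds of genes and cells) with
fC = 8 so structure is unambiguous; the end-to-end suite and the
reproduction script run the full 10,000-gene datasets at n = 1000–3000
with 5 replicate seeds per scenario, which keeps a complete run in the
minutes range on one CPU. Fold-change calibration is checked in
untruncated mode at n = 3000: the group-vs-rest ratio of library-size
normalized marker expression is compared to nominal fC within 15%,
excluding markers with fewer than 50 counts outside their group (a ratio
of near-zero means estimates nothing).

## What the simulation does and does not show

The generator emulates overdispersed counts, skewed baseline expression,
depth variation and clean group-specific marker structure. It does not
emulate batch effects, ambient RNA, doublets, correlated gene programs,
continuous or transitional states, or markers shared between types — all
of which make real rare-type detection harder. Passing benchmarks here
therefore give an optimistic bound: a pipeline that fails on these
simulations has little hope on real data, but success does not guarantee
field performance. The F1 levels observed at a given (rarity, fC, n)
should be read comparatively (between backends and design points) rather
than as absolute predictions.

## Known limitations

- The Seurat- and SIMLR-style backends are analogs built from those
  methods' published mechanisms, not wrappers of the R packages; exact
  agreement with any particular release is not expected. The registry is
  the supported route to benchmarking the real implementations.
- Louvain's resolution search is best-effort: on some graphs no resolution
  yields exactly the target count, and the nearest achievable partition is
  used (and recorded).
- The rare-type F1 at rarity 0.02 and n = 1000 rests on 20 cells and is
  intrinsically high-variance; occasional replicates score 0 when the
  rare cluster's contaminant count edges past its true-cell count and
  plurality matching hands the cluster to another type. Mean aggregation
  over replicates is the default for exactly this reason.
- Dropout is modeled but disabled in the benchmark scenarios; conclusions
  about heavily zero-inflated protocols require turning it on.
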