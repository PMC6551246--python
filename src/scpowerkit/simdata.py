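"""Simulation of labeled scRNA-seq count matrices.

The generative model is a minimal splat-style gamma-Poisson hierarchy:

1. baseline gene means are drawn from a gamma distribution;
2. each cell type upregulates a disjoint set of marker genes by a
   per-(marker, type) fold-change factor drawn from gamma(shape=fC, rate=1);
3. expected counts for a cell are its type's mean profile, renormalized to
   the cell's log-normal library size;
4. biological noise multiplies expected counts by a unit-mean gamma variate
   whose squared coefficient of variation is ``bcv_dispersion``;
5. observed counts are Poisson draws, optionally thinned by logistic dropout.

Every draw comes from one of five named substreams spawned from the master
seed, so the output is a pure function of :class:`SimulationParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.special import expit

__all__ = [
    "SimulationParams",
    "LabeledCountMatrix",
    "allocate_cells",
    "simulate_gene_means",
    "sample_fold_change",
    "select_markers",
    "inject_marker_means",
    "simulate_library_sizes",
    "simulate_counts",
    "generate_dataset",
]

# Fixed order of RNG substreams; appending a new stream never perturbs
# draws from existing ones.
_STREAMS = ("means", "markers", "fold_changes", "libsizes", "counts")

_TRUNCATION_MAX_ROUNDS = 1000


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or degenerate designs."""


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of one simulated dataset.

    Parameters
    ----------
    n_cells
        Number of cells (columns) to simulate.
    n_genes
        Number of genes (rows); 10,000 matches typical droplet panels.
    proportions
        Per-type mixture fractions; length defines the number of cell
        types ``m``. Must be positive and sum to 1.
    n_markers_per_type
        Number of marker genes upregulated in each type.
    fold_change
        Shape of the gamma(shape=fC, rate=1) distribution of marker
        fold-change factors; its mean equals ``fold_change``.
    mean_shape, mean_rate
        Gamma parameters of baseline gene means.
    libsize_location, libsize_scale
        Log-normal parameters of per-cell library size (expected total
        counts); the median library size is ``exp(libsize_location)``.
    bcv_dispersion
        Squared biological coefficient of variation; 0 gives pure Poisson
        counts.
    dropout_midpoint, dropout_shape
        Logistic dropout parameters (probability decreasing in log
        expected count); both ``None`` disables dropout.
    truncate_fc_below_one
        When True, fold-change factors < 1 are resampled so markers are
        strictly upregulated.
    seed
        Master seed; the dataset is bit-reproducible given identical params.
    """

    n_cells: int
    proportions: tuple = (0.1, 0.2, 0.2, 0.2, 0.3)
    n_genes: int = 10_000
    n_markers_per_type: int = 50
    fold_change: float = 2.0
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_location: float = math.log(20_000.0)
    libsize_scale: float = 0.2
    bcv_dispersion: float = 0.1
    dropout_midpoint: Optional[float] = None
    dropout_shape: Optional[float] = None
    truncate_fc_below_one: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "proportions", tuple(float(p) for p in self.proportions))
        p = np.asarray(self.proportions, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise SimulationError("proportions must list at least 2 cell types")
        if np.any(p <= 0):
            raise SimulationError("proportions must all be > 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise SimulationError(f"proportions must sum to 1 (got {p.sum():.12g})")
        if self.n_cells < p.size:
            raise SimulationError("n_cells must be at least the number of cell types")
        if self.n_genes <= 0 or self.n_markers_per_type <= 0:
            raise SimulationError("n_genes and n_markers_per_type must be positive")
        if self.n_markers_per_type * p.size > self.n_genes:
            raise SimulationError("n_markers_per_type * n_types exceeds n_genes")
        if self.fold_change < 1:
            raise SimulationError("fold_change must be >= 1")
        for name in ("mean_shape", "mean_rate", "libsize_scale"):
            if getattr(self, name) < 0 or (name != "libsize_scale" and getattr(self, name) == 0):
                raise SimulationError(f"{name} must be positive")
        if self.bcv_dispersion < 0:
            raise SimulationError("bcv_dispersion must be >= 0")
        if (self.dropout_midpoint is None) != (self.dropout_shape is None):
            raise SimulationError("dropout_midpoint and dropout_shape must be set together")
        if self.seed < 0:
            raise SimulationError("seed must be non-negative")

    @property
    def n_types(self) -> int:
        return len(self.proportions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["proportions"] = list(self.proportions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise SimulationError(f"unknown simulation parameter(s): {sorted(unknown)}")
        kwargs = dict(d)
        if "proportions" in kwargs:
            kwargs["proportions"] = tuple(kwargs["proportions"])
        return cls(**kwargs)


@dataclass
class LabeledCountMatrix:
    """Genes x cells integer count matrix with ground-truth cell-type labels.

    ``true_labels`` holds 1-based cell-type indices; ``marker_map`` maps each
    1-based type index to the 0-based gene indices of its markers (disjoint
    across types).
    """

    counts: sparse.csr_matrix
    gene_ids: list
    cell_ids: list
    true_labels: np.ndarray
    marker_map: dict = field(default_factory=dict)
    params: Optional[SimulationParams] = None

    def __post_init__(self):
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"gene_ids length {len(self.gene_ids)} != {g} matrix rows")
        if len(self.cell_ids) != c or self.true_labels.size != c:
            raise ValueError("cell_ids / true_labels length mismatch with matrix columns")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts contain negative entries")
        seen = set()
        for k, idx in self.marker_map.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= g):
                raise ValueError(f"marker index out of range for type {k}")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"marker sets overlap at gene index {sorted(overlap)[0]}")
            seen.update(idx.tolist())
            self.marker_map[k] = idx

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_types(self) -> int:
        return int(self.true_labels.max())


def _substreams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def allocate_cells(proportions: Sequence[float], n_cells: int) -> np.ndarray:
    """Apportion ``n_cells`` over types by largest remainder (deterministic).

    Exact quotas ``n_cells * p_k`` are floored; leftover cells go to the
    types with the largest fractional remainders, ties broken by lower type
    index. Every type must receive at least one cell.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size < 2:
        raise SimulationError("proportions must list at least 2 cell types")
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
        raise SimulationError("proportions must be positive and sum to 1")
    if n_cells < p.size:
        raise SimulationError("n_cells must be at least the number of cell types")
    quota = n_cells * p
    counts = np.floor(quota).astype(int)
    remainder = n_cells - counts.sum()
    # stable sort: descending fractional part, ties by lower index
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    if counts.min() < 1:
        raise SimulationError("n_cells too small for rarest proportion")
    assert counts.sum() == n_cells
    return counts


def simulate_gene_means(n_genes: int, mean_shape: float, mean_rate: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw baseline per-gene mean expression from gamma(shape, rate)."""
    if mean_shape <= 0 or mean_rate <= 0:
        raise SimulationError("gamma shape and rate must be positive")
    return rng.gamma(mean_shape, 1.0 / mean_rate, size=n_genes)


def sample_fold_change(fold_change: float, rng: np.random.Generator,
                       truncate_below_one: bool = True, size=None) -> np.ndarray:
    """Draw marker fold-change factors from gamma(shape=fC, rate=1).

    The untruncated distribution has mean ``fold_change``. With truncation,
    draws below 1 are resampled (bounded retries) so every marker is
    strictly upregulated.
    """
    if fold_change < 1:
        raise SimulationError("fold_change must be >= 1")
    out = np.atleast_1d(rng.gamma(fold_change, 1.0, size=size))
    if truncate_below_one:
        for _ in range(_TRUNCATION_MAX_ROUNDS):
            low = out < 1.0
            if not low.any():
                break
            out[low] = rng.gamma(fold_change, 1.0, size=int(low.sum()))
        else:
            raise SimulationError("fold-change truncation retry limit exceeded")
    return out if size is not None else float(out[0])


def select_markers(n_genes: int, n_types: int, n_markers_per_type: int,
                   rng: np.random.Generator) -> dict:
    """Sample disjoint marker-gene index sets, one per cell type (1-based keys)."""
    if n_markers_per_type * n_types > n_genes:
        raise SimulationError("not enough genes for requested marker sets")
    chosen = rng.choice(n_genes, size=n_markers_per_type * n_types, replace=False)
    return {k + 1: np.sort(chosen[k * n_markers_per_type:(k + 1) * n_markers_per_type])
            for k in range(n_types)}


def inject_marker_means(base_means: np.ndarray, marker_map: Mapping[int, np.ndarray],
                        fold_change: float, rng: np.random.Generator,
                        truncate_below_one: bool = True) -> np.ndarray:
    """Build the (types x genes) mean matrix with marker upregulation.

    For marker gene i of type k the type-k mean is ``factor * base_means[i]``
    with one gamma(fC, 1) factor per (marker, type) pair; the baseline mean
    stands in for the mean over cells outside k, which are unperturbed for
    that gene. Non-marker entries equal the baseline.
    """
    base_means = np.asarray(base_means, dtype=float)
    n_types = len(marker_map)
    adjusted = np.tile(base_means, (n_types, 1))
    for k in sorted(marker_map):
        idx = np.asarray(marker_map[k], dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= base_means.size):
            raise SimulationError(f"marker index out of range for type {k}")
        factors = sample_fold_change(fold_change, rng, truncate_below_one, size=idx.size)
        adjusted[k - 1, idx] = base_means[idx] * factors
    return adjusted


def simulate_library_sizes(n_cells: int, libsize_location: float, libsize_scale: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw per-cell expected total counts from a log-normal distribution."""
    if libsize_scale < 0:
        raise SimulationError("libsize_scale must be >= 0")
    return rng.lognormal(libsize_location, libsize_scale, size=n_cells)


def simulate_counts(adjusted_means: np.ndarray, library_sizes: np.ndarray,
                    type_of_cell: np.ndarray, bcv_dispersion: float,
                    rng: np.random.Generator,
                    dropout_midpoint: Optional[float] = None,
                    dropout_shape: Optional[float] = None) -> sparse.csr_matrix:
    """Sample the genes x cells count matrix.

    Cell j of type k gets rate ``lambda_ij = mean_k(i) * L_j / sum_i mean_k(i)``
    so column sums concentrate around the library size L_j. Biological noise
    multiplies rates by gamma variates with unit mean and squared CV
    ``bcv_dispersion``; counts are Poisson; dropout (if enabled) zeroes an
    entry with probability ``sigmoid(dropout_shape * (dropout_midpoint -
    log(lambda)))`` — decreasing in expression.
    """
    adjusted_means = np.asarray(adjusted_means, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    type_of_cell = np.asarray(type_of_cell, dtype=int)
    if bcv_dispersion < 0:
        raise SimulationError("bcv_dispersion must be >= 0")
    n_genes = adjusted_means.shape[1]
    n_cells = library_sizes.size
    profiles = adjusted_means / adjusted_means.sum(axis=1, keepdims=True)
    counts = np.empty((n_genes, n_cells), dtype=np.int32)
    # process per type to keep the dense rate block small
    for k in range(adjusted_means.shape[0]):
        cols = np.flatnonzero(type_of_cell == k + 1)
        if cols.size == 0:
            continue
        lam = np.outer(profiles[k], library_sizes[cols])
        if not np.all(np.isfinite(lam)):
            raise SimulationError("non-finite Poisson rate encountered")
        if bcv_dispersion > 0:
            lam = lam * rng.gamma(1.0 / bcv_dispersion, bcv_dispersion, size=lam.shape)
        block = rng.poisson(lam)
        if dropout_midpoint is not None and dropout_shape is not None:
            with np.errstate(divide="ignore"):
                p_drop = expit(dropout_shape * (dropout_midpoint - np.log(lam)))
            block[rng.random(lam.shape) < p_drop] = 0
        counts[:, cols] = block
    return sparse.csr_matrix(counts)


def generate_dataset(params: SimulationParams) -> LabeledCountMatrix:
    """Simulate a complete labeled dataset from ``params`` (seed-deterministic)."""
    rngs = _substreams(params.seed)
    per_type = allocate_cells(params.proportions, params.n_cells)
    type_of_cell = np.repeat(np.arange(1, params.n_types + 1), per_type)
    base_means = simulate_gene_means(params.n_genes, params.mean_shape,
                                     params.mean_rate, rngs["means"])
    marker_map = select_markers(params.n_genes, params.n_types,
                                params.n_markers_per_type, rngs["markers"])
    adjusted = inject_marker_means(base_means, marker_map, params.fold_change,
                                   rngs["fold_changes"], params.truncate_fc_below_one)
    libsizes = simulate_library_sizes(params.n_cells, params.libsize_location,
                                      params.libsize_scale, rngs["libsizes"])
    counts = simulate_counts(adjusted, libsizes, type_of_cell, params.bcv_dispersion,
                             rngs["counts"], params.dropout_midpoint, params.dropout_shape)
    width_g = len(str(params.n_genes))
    width_c = len(str(params.n_cells))
    gene_ids = [f"G{i + 1:0{width_g}d}" for i in range(params.n_genes)]
    cell_ids = [f"C{j + 1:0{width_c}d}" for j in range(params.n_cells)]
    return LabeledCountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                              true_labels=type_of_cell, marker_map=marker_map,
                              params=params)
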