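"""Factorial simulation-clustering-evaluation grids and sample-size answers.

A :class:`GridSpec` crosses cell-type proportion sets, cell numbers and
marker fold changes; each grid cell is simulated (with replicates under
derived seeds), clustered by every configured backend, and scored. The
long-format result — one row per (grid cell, backend, replicate) — is the
power table from which the two design answers are read: the smallest cell
number whose aggregated F1 clears a user threshold, and the backend ranking
for a scenario.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import backends as _backends
from .backends import BackendSpec, preprocess, run_backend
from .evalmetrics import evaluate
from .simdata import SimulationParams, generate_dataset

__all__ = [
    "GridSpec",
    "table1_grid",
    "derive_seed",
    "enumerate_grid",
    "run_grid",
    "min_cells_for_threshold",
    "select_best_pipeline",
    "NOT_ACHIEVED",
]

log = logging.getLogger("scpowerkit.design")

#: Explicit sentinel for "no tested cell number reaches the threshold".
NOT_ACHIEVED = "not achieved"

POWER_COLUMNS = ["backend_name", "rarity", "fC", "n_cells", "replicate",
                 "rare_type_f1", "macro_f1", "realized_cluster_count", "seed"]


class DesignError(ValueError):
    """Raised for malformed grids or queries."""


@dataclass
class GridSpec:
    """Factorial design: proportions x cell numbers x fold changes."""

    proportion_sets: Sequence[Sequence[float]]
    n_cells_levels: Sequence[int]
    fold_changes: Sequence[float]
    n_genes: int = 10_000
    n_markers_per_type: int = 50
    backends: Sequence[BackendSpec] = field(default_factory=lambda: [
        BackendSpec("kmeans"), BackendSpec("snn_louvain"), BackendSpec("mk_spectral")])
    replicates: int = 5
    master_seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.proportion_sets or not self.n_cells_levels or not self.fold_changes:
            raise DesignError("every grid level list must be non-empty")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        self.backends = [b if isinstance(b, BackendSpec) else BackendSpec(str(b))
                         for b in self.backends]

    @property
    def grid_size(self) -> int:
        return len(self.proportion_sets) * len(self.n_cells_levels) * len(self.fold_changes)


def table1_grid(replicates: int = 5, master_seed: int = 0, **overrides) -> GridSpec:
    """The benchmark design: three 5-type mixtures with a rare type at
    0.1 / 0.05 / 0.02, n in {1000, 2000, 3000}, fC in {2, 4, 8} — 27 cells."""
    return GridSpec(
        proportion_sets=[(0.1, 0.2, 0.2, 0.2, 0.3),
                         (0.05, 0.35, 0.2, 0.2, 0.2),
                         (0.02, 0.2, 0.2, 0.2, 0.38)],
        n_cells_levels=[1000, 2000, 3000],
        fold_changes=[2.0, 4.0, 8.0],
        replicates=replicates, master_seed=master_seed, **overrides)


def derive_seed(master_seed: int, *coords) -> int:
    """Stable per-cell seed from the master seed and cell coordinates.

    Uses SHA-256 so the value is identical across platforms and sessions;
    result fits in 31 bits.
    """
    key = ":".join(str(c) for c in (master_seed,) + coords)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def enumerate_grid(spec: GridSpec, replicate: int = 0) -> List[SimulationParams]:
    """One :class:`SimulationParams` per factorial cell for one replicate.

    Ordering is deterministic: proportion sets outermost, cell numbers, then
    fold changes innermost. Seeds derive from the master seed and the cell
    coordinates, so replicates differ but re-runs repeat exactly.
    """
    out = []
    for pi, props in enumerate(spec.proportion_sets):
        for ni, n_cells in enumerate(spec.n_cells_levels):
            for fi, fc in enumerate(spec.fold_changes):
                out.append(SimulationParams(
                    n_cells=int(n_cells), proportions=tuple(props),
                    n_genes=spec.n_genes,
                    n_markers_per_type=spec.n_markers_per_type,
                    fold_change=float(fc),
                    seed=derive_seed(spec.master_seed, pi, ni, fi, replicate),
                    **spec.sim_overrides))
    return out


def _load_ledger(path: Optional[Path]) -> pd.DataFrame:
    if path is not None and Path(path).exists():
        return pd.read_csv(path, sep="\t")
    return pd.DataFrame(columns=POWER_COLUMNS)


def run_grid(spec: GridSpec, ledger_path=None, abort_on_error: bool = False,
             preprocess_kwargs: Optional[dict] = None) -> pd.DataFrame:
    """Execute the full grid x backends x replicates and return the power table.

    Each dataset is simulated once and preprocessed once; every backend then
    clusters the shared embedding. A failure of one backend on one dataset
    is logged and recorded as a missing row (unless ``abort_on_error``).
    With ``ledger_path``, completed rows are appended as they finish and
    skipped on re-run, making long grids resumable.
    """
    for b in spec.backends:
        _backends.get_backend(b.backend_name)  # fail before simulating
    ledger_path = Path(ledger_path) if ledger_path is not None else None
    done = _load_ledger(ledger_path)
    done_keys = set(zip(done["backend_name"], done["rarity"], done["fC"],
                        done["n_cells"], done["replicate"])) if len(done) else set()
    rows = list(done.to_dict("records"))
    pk = preprocess_kwargs or {}
    for rep in range(spec.replicates):
        for params in enumerate_grid(spec, replicate=rep):
            rarity = min(params.proportions)
            wanted = [b for b in spec.backends
                      if (b.backend_name, rarity, params.fold_change,
                          params.n_cells, rep) not in done_keys]
            if not wanted:
                continue
            dataset = generate_dataset(params)
            embedding = preprocess(dataset, **pk)
            m = params.n_types
            for b in wanted:
                t0 = time.perf_counter()
                try:
                    assignment = run_backend(b, embedding, m_target=m, seed=params.seed)
                    score = evaluate(dataset.true_labels, assignment)
                except Exception as exc:  # record-and-continue policy
                    if abort_on_error:
                        raise
                    log.error("status=failed backend=%s rarity=%s fC=%s n=%s rep=%s err=%r",
                              b.backend_name, rarity, params.fold_change,
                              params.n_cells, rep, exc)
                    continue
                row = {"backend_name": b.backend_name, "rarity": rarity,
                       "fC": params.fold_change, "n_cells": params.n_cells,
                       "replicate": rep,
                       "rare_type_f1": score.rare_type_f1,
                       "macro_f1": score.macro_f1,
                       "realized_cluster_count": int(score.contingency.shape[1]),
                       "seed": params.seed}
                rows.append(row)
                log.info("status=done backend=%s rarity=%s fC=%s n=%s rep=%s seed=%d "
                         "rare_f1=%.3f macro_f1=%.3f wall=%.1fs",
                         b.backend_name, rarity, params.fold_change, params.n_cells,
                         rep, params.seed, score.rare_type_f1, score.macro_f1,
                         time.perf_counter() - t0)
                if ledger_path is not None:
                    pd.DataFrame([row])[POWER_COLUMNS].to_csv(
                        ledger_path, sep="\t", index=False, mode="a",
                        header=not ledger_path.exists())
    table = pd.DataFrame(rows, columns=POWER_COLUMNS)
    return table.sort_values(["backend_name", "rarity", "fC", "n_cells", "replicate"],
                             ignore_index=True)


def _aggregate(power_table: pd.DataFrame, aggregator: str) -> pd.DataFrame:
    if aggregator not in ("mean", "median"):
        raise DesignError("aggregator must be 'mean' or 'median'")
    return (power_table
            .groupby(["backend_name", "rarity", "fC", "n_cells"], as_index=False)
            .agg(rare_type_f1=("rare_type_f1", aggregator),
                 macro_f1=("macro_f1", aggregator)))


def min_cells_for_threshold(power_table: pd.DataFrame, threshold: float,
                            aggregator: str = "mean",
                            metric: str = "rare_type_f1") -> pd.DataFrame:
    """Smallest tested cell number whose aggregated F1 reaches ``threshold``.

    Returns one row per (backend, rarity, fC) with ``min_cells`` holding the
    first n-level (scanned in increasing order) meeting the threshold, or
    the explicit string ``"not achieved"``.
    """
    if not (0.0 < threshold <= 1.0):
        raise DesignError("threshold must lie in (0, 1]")
    agg = _aggregate(power_table, aggregator)
    out = []
    for (backend, rarity, fc), grp in agg.groupby(["backend_name", "rarity", "fC"]):
        grp = grp.sort_values("n_cells")
        hit = grp[grp[metric] >= threshold]
        out.append({"backend_name": backend, "rarity": rarity, "fC": fc,
                    "min_cells": int(hit["n_cells"].iloc[0]) if len(hit) else NOT_ACHIEVED,
                    "best_f1": float(grp[metric].max())})
    return pd.DataFrame(out)


def select_best_pipeline(power_table: pd.DataFrame, rarity: float, fC: float,
                         n_cells: int, aggregator: str = "mean") -> pd.DataFrame:
    """Rank backends for one scenario by aggregated rare-type F1.

    Ties break by macro F1 then backend name; the full ranking is returned,
    winner first.
    """
    agg = _aggregate(power_table, aggregator)
    sel = agg[(agg["rarity"] == rarity) & (agg["fC"] == fC) & (agg["n_cells"] == n_cells)]
    if sel.empty:
        raise DesignError(
            f"no rows for scenario rarity={rarity}, fC={fC}, n_cells={n_cells}")
    sel = sel.sort_values(["rare_type_f1", "macro_f1", "backend_name"],
                          ascending=[False, False, True], ignore_index=True)
    sel.insert(0, "rank", np.arange(1, len(sel) + 1))
    return sel
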