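"""Dataset bundles on disk and configuration files.

A dataset bundle is a directory in the familiar MTX-plus-sidecars layout:

    counts.mtx    Matrix Market coordinate integer, genes as rows, 1-based
    genes.tsv     one gene id per line
    cells.tsv     cell id TAB true-type label (1-based integer)
    markers.tsv   gene id TAB type index (optional; absent for external data)
    params.json   the SimulationParams that produced the bundle (optional)

Indices are 1-based only inside counts.mtx (the format's convention);
everything in memory is 0-based. Entry order in counts.mtx is row-major, so
write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from scipy import io as spio
from scipy import sparse

from .simdata import LabeledCountMatrix, SimulationParams

__all__ = ["write_bundle", "read_bundle", "load_config", "BundleError"]

MEMBER_FILES = ("counts.mtx", "genes.tsv", "cells.tsv")


class BundleError(ValueError):
    """Raised for malformed or inconsistent dataset bundles."""


def write_bundle(matrix: LabeledCountMatrix, path, overwrite: bool = False) -> Path:
    """Write a dataset bundle; refuses a non-empty directory unless
    ``overwrite`` is set."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise BundleError(f"directory {path} is not empty (pass overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)
    counts = sparse.csr_matrix(matrix.counts)
    counts.sum_duplicates()
    counts.sort_indices()
    coo = counts.tocoo()  # CSR -> COO is row-major ordered
    spio.mmwrite(path / "counts.mtx", coo, field="integer")
    (path / "genes.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    (path / "cells.tsv").write_text(
        "".join(f"{c}\t{int(t)}\n" for c, t in zip(matrix.cell_ids, matrix.true_labels)))
    if matrix.marker_map:
        lines = []
        for k in sorted(matrix.marker_map):
            for gi in matrix.marker_map[k]:
                lines.append(f"{matrix.gene_ids[int(gi)]}\t{int(k)}\n")
        (path / "markers.tsv").write_text("".join(lines))
    if matrix.params is not None:
        (path / "params.json").write_text(
            json.dumps(matrix.params.to_dict(), indent=2, sort_keys=True) + "\n")
    return path


def _read_mtx(path: Path) -> sparse.csr_matrix:
    try:
        mat = spio.mmread(path)
    except Exception as exc:
        raise BundleError(f"cannot parse {path.name}: {exc}") from exc
    data = mat.data if sparse.issparse(mat) else np.asarray(mat).ravel()
    if data.size and np.any(data < 0):
        raise BundleError(f"{path.name}: negative count entry")
    if data.size and not np.allclose(data, np.round(data)):
        raise BundleError(f"{path.name}: non-integer count entry")
    return sparse.csr_matrix(mat, dtype=np.int64)


def read_bundle(path) -> LabeledCountMatrix:
    """Load a dataset bundle, validating dimensions and label values.

    ``markers.tsv`` and ``params.json`` are optional so externally produced
    bundles load with an empty marker map.
    """
    path = Path(path)
    for member in MEMBER_FILES:
        if not (path / member).exists():
            raise BundleError(f"missing bundle member {member} in {path}")
    counts = _read_mtx(path / "counts.mtx")
    gene_ids = (path / "genes.tsv").read_text().splitlines()
    n_genes, n_cells = counts.shape
    if len(gene_ids) != n_genes:
        raise BundleError(
            f"genes.tsv has {len(gene_ids)} lines but counts.mtx declares {n_genes} rows")
    cell_ids, labels = [], []
    for lineno, line in enumerate((path / "cells.tsv").read_text().splitlines(), 1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise BundleError(f"cells.tsv line {lineno}: expected 'cell_id<TAB>label'")
        cell_ids.append(parts[0])
        try:
            labels.append(int(parts[1]))
        except ValueError:
            raise BundleError(
                f"cells.tsv line {lineno}: unknown label {parts[1]!r} (integer expected)")
    if len(cell_ids) != n_cells:
        raise BundleError(
            f"cells.tsv has {len(cell_ids)} lines but counts.mtx declares {n_cells} columns")
    marker_map = {}
    if (path / "markers.tsv").exists():
        gene_index = {g: i for i, g in enumerate(gene_ids)}
        groups: dict = {}
        for lineno, line in enumerate((path / "markers.tsv").read_text().splitlines(), 1):
            parts = line.split("\t")
            if len(parts) != 2 or parts[0] not in gene_index:
                raise BundleError(f"markers.tsv line {lineno}: unknown gene or bad format")
            groups.setdefault(int(parts[1]), []).append(gene_index[parts[0]])
        marker_map = {k: np.sort(np.array(v, dtype=int)) for k, v in groups.items()}
    params = None
    if (path / "params.json").exists():
        params = SimulationParams.from_dict(json.loads((path / "params.json").read_text()))
    return LabeledCountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                              true_labels=np.asarray(labels, dtype=int),
                              marker_map=marker_map, params=params)


def load_config(path) -> dict:
    """Parse a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise BundleError(f"config {path} must be a mapping of field names to values")
    return cfg
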