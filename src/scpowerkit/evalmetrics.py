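"""Scoring cluster assignments against ground-truth cell-type labels.

Predicted clusters carry arbitrary ids, so scoring proceeds in three steps:
build the type x cluster contingency table, assign each cluster to the
cell type holding the plurality of its cells (many clusters may map to one
type), then pool true/false positives per type to get precision, recall and
F1 = 2PR/(P+R). The headline number for rare-population detection is the F1
of the least-abundant type; the unweighted macro mean is reported alongside.

All zero-denominator cases (a type with no mapped cluster, precision and
recall both zero) score 0, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .backends import ClusterAssignment

__all__ = [
    "TypeScoreTable",
    "contingency_table",
    "match_clusters_to_types",
    "precision_recall",
    "f1_score",
    "evaluate",
]


class MetricError(ValueError):
    """Raised for malformed label vectors or metric inputs."""


@dataclass
class TypeScoreTable:
    """Per-type precision/recall/F1 plus rare-type and macro summaries."""

    per_type: pd.DataFrame
    rare_type_f1: float
    macro_f1: float
    contingency: pd.DataFrame
    mapping: Dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.per_type.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {"rare_type_f1": self.rare_type_f1, "macro_f1": self.macro_f1,
                "n_clusters": int(self.contingency.shape[1])}


def contingency_table(true_labels, predicted_labels) -> pd.DataFrame:
    """Type x cluster overlap counts; rows indexed by true type, columns by
    predicted cluster id, both sorted ascending."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise MetricError(
            f"label vectors differ in length: {true_labels.size} vs {predicted_labels.size}")
    if true_labels.size == 0:
        raise MetricError("empty label vectors")
    return pd.crosstab(pd.Series(true_labels, name="type"),
                       pd.Series(predicted_labels, name="cluster")).sort_index(
        axis=0).sort_index(axis=1)


def match_clusters_to_types(contingency: pd.DataFrame) -> Dict:
    """Plurality matching: each cluster goes to the type holding most of its
    cells; ties break toward the lower type index. Many-to-one is allowed."""
    if contingency.size == 0:
        raise MetricError("empty contingency table")
    # idxmax returns the first (lowest) index on ties
    return {c: contingency[c].idxmax() for c in contingency.columns}


def _match_hungarian(contingency: pd.DataFrame) -> Dict:
    """One-to-one matching maximizing total overlap; surplus clusters stay
    unmapped (their cells count against recall only)."""
    cost = -contingency.to_numpy(dtype=float)
    rows, cols = linear_sum_assignment(cost)
    return {contingency.columns[c]: contingency.index[r] for r, c in zip(rows, cols)}


def precision_recall(contingency: pd.DataFrame, mapping: Dict,
                     type_k) -> Tuple[float, float]:
    """Pooled precision/recall for one type over all clusters mapped to it.

    TP are type-k cells inside those clusters, FP the other cells inside
    them, FN the type-k cells elsewhere. A type with no mapped cluster
    scores (0, 0).
    """
    if type_k not in contingency.index:
        raise MetricError(f"type {type_k!r} not present in contingency table")
    clusters = [c for c, t in mapping.items() if t == type_k]
    total_k = int(contingency.loc[type_k].sum())
    if not clusters:
        return 0.0, 0.0
    tp = int(contingency.loc[type_k, clusters].sum())
    pooled = int(contingency[clusters].to_numpy().sum())
    fp = pooled - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / total_k if total_k > 0 else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both inputs are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise MetricError("precision and recall must lie in [0, 1]")
    denom = precision + recall
    return 0.0 if denom == 0 else 2.0 * precision * recall / denom


def evaluate(true_labels, assignment, matching: str = "plurality") -> TypeScoreTable:
    """Score a cluster assignment against true labels.

    Parameters
    ----------
    true_labels
        Ground-truth type index per cell.
    assignment
        :class:`ClusterAssignment` or a raw predicted-label vector.
    matching
        ``"plurality"`` (default; many-to-one) or ``"hungarian"``
        (one-to-one, for sensitivity analysis).

    Returns
    -------
    :class:`TypeScoreTable` with one row per type, the rare type taken as
    the one with the fewest true cells (ties toward the lower index).
    """
    predicted = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    cont = contingency_table(true_labels, predicted)
    if matching == "plurality":
        mapping = match_clusters_to_types(cont)
    elif matching == "hungarian":
        mapping = _match_hungarian(cont)
    else:
        raise MetricError(f"unknown matching rule {matching!r}")
    rows = []
    for k in cont.index:
        p, r = precision_recall(cont, mapping, k)
        rows.append({"type": k,
                     "matched_clusters": sorted(c for c, t in mapping.items() if t == k),
                     "true_count": int(cont.loc[k].sum()),
                     "precision": p, "recall": r, "f1": f1_score(p, r)})
    per_type = pd.DataFrame(rows)
    rare_idx = int(per_type["true_count"].idxmin())  # first minimum -> lowest type
    return TypeScoreTable(per_type=per_type,
                          rare_type_f1=float(per_type.loc[rare_idx, "f1"]),
                          macro_f1=float(per_type["f1"].mean()),
                          contingency=cont, mapping=mapping)
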