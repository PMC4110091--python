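"""Transcriptome-based terminal-cell reclassification.

Cells are grouped by agglomerative hierarchical clustering on pairwise
Euclidean distances between expression profiles, and the dendrogram is cut
to a requested number of groups; the groups serve as expression-based cell
types.  Partitions are compared by mutual information in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import mutual_info_score

from .errors import DegenerateInputError, MappingError
from .lineage import CellTypeCensus

__all__ = [
    "Partition",
    "cluster_cells",
    "partition_mutual_information",
    "partition_entropy",
    "partition_census",
    "load_expression",
]


@dataclass(frozen=True)
class Partition:
    """cell -> cluster label, with the linkage recorded as metadata."""

    labels: Dict[str, int]
    method: str = "given"

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    @property
    def cells(self):
        return sorted(self.labels)

    def sizes(self) -> Dict[int, int]:
        out: Dict[int, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out


def load_expression(path) -> pd.DataFrame:
    """Cells x genes table; first column = cell ids, header row = genes."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise MappingError(f"{path}: missing expression values")
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise DegenerateInputError("expression matrix needs >= 2 cells, >= 1 gene")
    return df


def cluster_cells(expr: pd.DataFrame, k: int, method: str = "complete"
                  ) -> Partition:
    """Cut a hierarchical clustering of expression profiles into k groups.

    Cells are sorted lexicographically before clustering so that distance
    ties resolve deterministically.
    """
    if not (2 <= k <= expr.shape[0]):
        raise DegenerateInputError(f"k = {k} outside [2, {expr.shape[0]}]")
    expr = expr.sort_index()
    if k == expr.shape[0]:
        labels = {c: i + 1 for i, c in enumerate(expr.index)}
        return Partition(labels=labels, method=method)
    Z = linkage(pdist(expr.to_numpy(dtype=float), metric="euclidean"),
                method=method)
    flat = fcluster(Z, t=k, criterion="maxclust")
    return Partition(labels=dict(zip(expr.index, map(int, flat))), method=method)


def partition_mutual_information(p1: Partition, p2: Partition) -> float:
    """Mutual information between two partitions of the same cells, in bits."""
    if set(p1.labels) != set(p2.labels):
        raise MappingError("partitions cover different cell sets")
    cells = sorted(p1.labels)
    a = [p1.labels[c] for c in cells]
    b = [p2.labels[c] for c in cells]
    return float(mutual_info_score(a, b) / log(2))


def partition_entropy(p: Partition) -> float:
    """Shannon entropy of cluster sizes, in bits."""
    sizes = np.array(list(p.sizes().values()), dtype=float)
    q = sizes / sizes.sum()
    return float(-(q * np.log2(q)).sum())


def partition_census(partition: Partition) -> CellTypeCensus:
    """Cluster sizes as a cell-type census (no excluded types)."""
    if not partition.labels:
        raise DegenerateInputError("empty partition")
    counts: Dict[str, int] = {}
    for lab in partition.labels.values():
        key = f"c{lab}"
        counts[key] = counts.get(key, 0) + 1
    return CellTypeCensus(counts=counts)


def partition_type_map(partition: Partition) -> Dict[str, str]:
    """cell -> cluster-name map usable as lineage terminal types."""
    return {c: f"c{lab}" for c, lab in partition.labels.items()}
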