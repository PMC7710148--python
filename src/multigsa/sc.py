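"""Cluster-level pathway analysis for scRNA-seq.

Single cells are too sparse for per-cell pathway statistics; the engine
instead aggregates cells into pseudo-bulk profiles — the mean expression of
each gene within a cluster — and scores the cluster profiles with the
single-sample enrichment method.  This yields one pathway-level expression
value per cell cluster; z-scoring each pathway across clusters highlights
which cluster drives it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import GeneSetCollection
from .errors import AnalysisError
from .gsa import ssgsea_scores

__all__ = [
    "ClusterAssignment",
    "pseudobulk",
    "analyze_clusters",
    "zscore_by_pathway",
]


class ClusterAssignment:
    """cell id -> cluster label; every cell carries exactly one label."""

    def __init__(self, labels: dict[str, str]):
        self._labels = dict(labels)
        if not self._labels:
            raise AnalysisError("cluster assignment is empty")

    @classmethod
    def from_tsv(cls, path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if df.shape[1] != 2:
            raise AnalysisError(
                f"cluster assignment needs 2 columns, got {df.shape[1]}"
            )
        first = tuple(df.iloc[0])
        if first in (("cell_id", "cluster"), ("cell", "cluster")):
            df = df.iloc[1:]
        if df[0].duplicated().any():
            dup = df[0][df[0].duplicated()].iloc[0]
            raise AnalysisError(f"cell {dup!r} assigned more than once")
        return cls(dict(zip(df[0], df[1])))

    @property
    def labels(self) -> dict[str, str]:
        return dict(self._labels)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cell, cl in self._labels.items():
            out.setdefault(cl, []).append(cell)
        return out

    def __len__(self) -> int:
        return len(self._labels)


def pseudobulk(
    matrix: pd.DataFrame,
    clusters: ClusterAssignment,
    stat: str = "mean",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genes-by-clusters matrix of within-cluster mean expression.

    Cells present in the assignment but absent from the matrix are ignored;
    a cluster left with zero cells is dropped with a warning entry in the
    returned size log, and losing every cluster is an error.  Returns the
    aggregated matrix and the per-cluster cell counts actually used.
    """
    if stat != "mean":
        raise AnalysisError(f"unsupported aggregation {stat!r}")
    cells_in_matrix = set(matrix.columns)
    sizes: dict[str, int] = {}
    cols = {}
    for label, cells in sorted(clusters.clusters().items()):
        usable = [c for c in cells if c in cells_in_matrix]
        if not usable:
            sizes[label] = 0
            continue
        sizes[label] = len(usable)
        cols[label] = matrix[usable].mean(axis=1)
    if not cols:
        raise AnalysisError("no cluster retained any cell present in the matrix")
    return pd.DataFrame(cols), sizes


def analyze_clusters(
    matrix: pd.DataFrame,
    clusters: ClusterAssignment,
    collection: GeneSetCollection,
    *,
    alpha: float = 0.25,
    use_kernel: bool = False,
    kernel: str | None = None,
    normalize: bool = True,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Pseudo-bulk aggregation followed by single-sample pathway scoring.

    Returns one pathway-level score per cluster (pathways by clusters).
    Pathways with no member in the matrix are absent from the output.  The
    mean is taken on the matrix as provided — the engine does not second-
    guess the input scale — but a matrix whose maximum is below 50 looks
    log-transformed and triggers a warning.
    """
    pb, _sizes = pseudobulk(matrix, clusters)
    if matrix.to_numpy().max() < 50:
        warnings.warn(
            "matrix max < 50: input may already be log-scaled; cluster "
            "means are computed on the values as provided",
            stacklevel=2,
        )
    return ssgsea_scores(
        pb,
        collection,
        alpha=alpha,
        use_kernel=use_kernel,
        kernel=kernel,
        normalize=normalize,
        min_set_size=min_set_size,
    )


def zscore_by_pathway(scores: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each pathway's scores to unit sd across clusters.

    Uses the sample (n-1) standard deviation, so a row [1, 2, 3] maps to
    [-1, 0, 1].  Constant rows become all-zero; a single-column matrix is an
    error (no across-cluster variation to standardize).
    """
    if scores.shape[1] < 2:
        raise AnalysisError("z-scoring needs at least 2 clusters")
    X = scores.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=scores.index, columns=scores.columns)
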