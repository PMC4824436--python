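"""Unsupervised multivariate views: PCA and Spearman/average-linkage HCA.

PCA is computed by singular value decomposition of the centered (and by
default autoscaled) matrix with a deterministic sign convention, so score
plots are reproducible run to run. Hierarchical clustering uses
1 - Spearman rank correlation as the dissimilarity and average (UPGMA)
linkage — the standard metabolomics heatmap recipe, which is invariant to
any monotone transform of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_data import AbundanceTable, TableError

__all__ = ["PcaResult", "Dendrogram", "run_pca", "cluster_hca"]


@dataclass
class PcaResult:
    scores: pd.DataFrame = field(repr=False)     # samples x components
    loadings: pd.DataFrame = field(repr=False)   # metabolites x components
    variance_fraction: np.ndarray = field(repr=False)
    scaling: str = "autoscale"

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class Dendrogram:
    """Merge list in scipy cluster numbering: original items are
    0..n-1, the i-th merge creates cluster n+i at the given height."""

    merges: list[tuple[int, int, float]]
    labels: list[str]
    leaf_order: list[int]
    metric: str = "spearman"
    linkage: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Newick text with merge heights as cumulative node depths
        (branch length = parent height - child height)."""
        heights = {i: 0.0 for i in range(self.n_leaves)}
        nodes = {i: _quote(self.labels[i]) for i in range(self.n_leaves)}
        for k, (a, b, h) in enumerate(self.merges):
            nid = self.n_leaves + k
            branches = ",".join(
                f"{nodes[c]}:{h - heights[c]:.10g}" for c in (a, b)
            )
            nodes[nid] = f"({branches})"
            heights[nid] = h
        return nodes[self.n_leaves + len(self.merges) - 1] + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def run_pca(
    table: AbundanceTable,
    scaling: str = "autoscale",
    n_components: int | None = None,
) -> PcaResult:
    """PCA of the samples x metabolites matrix via SVD.

    ``scaling="autoscale"`` (default) centers and scales each metabolite
    to unit variance — the usual choice when intensities span orders of
    magnitude; ``scaling="center"`` reproduces covariance-matrix PCA.
    Component signs follow the convention that the largest-magnitude
    loading of each component is positive.
    """
    if scaling not in {"center", "autoscale"}:
        raise TableError(f"unknown scaling {scaling!r}")
    if table.n_samples < 2 or table.n_metabolites < 2:
        raise TableError("PCA needs at least 2 samples and 2 metabolites")
    if table.n_missing():
        raise TableError("PCA input must have no missing values")

    X = table.data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        flat = np.flatnonzero(sd == 0.0)
        if flat.size:
            raise TableError(
                "zero-variance metabolite(s) under autoscale: "
                + ", ".join(table.metabolite_names[i] for i in flat)
            )
        X = X / sd

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if n_components is not None:
        U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: largest-|loading| entry positive per component
    for k in range(len(S)):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    total = float(np.sum(np.linalg.svd(X, compute_uv=False) ** 2))
    comp_names = [f"PC{k + 1}" for k in range(len(S))]
    return PcaResult(
        scores=pd.DataFrame(
            U * S, index=table.sample_ids, columns=comp_names
        ),
        loadings=pd.DataFrame(
            Vt.T, index=table.metabolite_names, columns=comp_names
        ),
        variance_fraction=S**2 / total,
        scaling=scaling,
    )


def _spearman_dissimilarity(matrix: np.ndarray, labels: list[str]) -> np.ndarray:
    """1 - Spearman rank correlation between rows, midranks for ties."""
    from scipy.stats import rankdata

    sd = matrix.std(axis=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        raise TableError(
            "constant profile(s), Spearman undefined: "
            + ", ".join(labels[i] for i in flat)
        )
    ranks = np.apply_along_axis(rankdata, 1, matrix)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    # numeric symmetry for squareform
    return np.clip((d + d.T) / 2.0, 0.0, None)


def cluster_hca(table: AbundanceTable, axis: str = "samples") -> Dendrogram:
    """Average-linkage hierarchical clustering on 1 - Spearman distances,
    along either the sample axis or the metabolite axis."""
    if axis not in {"samples", "metabolites"}:
        raise TableError(f"unknown axis {axis!r}")
    if table.n_missing():
        raise TableError("HCA input must have no missing values")
    matrix = table.data.to_numpy(dtype=float)
    labels = table.sample_ids
    if axis == "metabolites":
        matrix = matrix.T
        labels = table.metabolite_names
    if matrix.shape[0] < 3:
        raise TableError("HCA needs at least 3 items")

    d = _spearman_dissimilarity(matrix, labels)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    leaf_order = [int(i) for i in hierarchy.leaves_list(Z)]
    return Dendrogram(merges=merges, labels=list(labels), leaf_order=leaf_order)
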