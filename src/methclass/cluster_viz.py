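"""Exploratory hierarchical clustering and heatmap rendering.

Samples (rows) are clustered over the most variable autosomal loci using
pairwise Manhattan (L1) distance and average linkage (UPGMA): each merge
height equals the average inter-cluster distance.  Heatmaps use the
blue/yellow convention — blue methylated, yellow unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .datatypes import BetaMatrix

__all__ = ["Dendrogram", "top_variance_loci", "hcluster", "heatmap_export"]


@dataclass
class Dendrogram:
    merges: np.ndarray        # scipy linkage matrix: (n-1) x 4
    leaf_order: np.ndarray    # permutation of input rows
    labels: list[str]
    metric: str = "manhattan"
    linkage_method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def top_variance_loci(beta: BetaMatrix, k: int) -> list[str]:
    """The k loci with the largest across-sample variance; ties broken
    deterministically by locus ID."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > beta.n_loci:
        raise ValueError(f"k={k} exceeds the {beta.n_loci} available loci")
    var = beta.values.var(axis=0, ddof=1)
    order = sorted(beta.locus_ids, key=lambda l: (-var[l], l))
    return order[:k]


def hcluster(
    matrix, metric: str = "manhattan", linkage_method: str = "average",
    labels: list[str] | None = None,
) -> Dendrogram:
    """UPGMA (or complete-linkage) dendrogram on L1 distances.

    ``matrix`` is observations x features; missing values are an error
    (mean-impute upstream)."""
    if isinstance(matrix, BetaMatrix):
        labels = labels or matrix.sample_ids
        matrix = matrix.to_numpy()
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(arr).any():
        raise ValueError("matrix contains NaN; impute before clustering")
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    scipy_metric = {"manhattan": "cityblock"}.get(metric, metric)
    Z = linkage(pdist(arr, metric=scipy_metric), method=linkage_method)
    if labels is None:
        labels = [str(i) for i in range(arr.shape[0])]
    return Dendrogram(Z, leaves_list(Z), list(labels), metric, linkage_method)


def heatmap_export(
    matrix,
    row_order,
    col_order,
    image_path=None,
    tsv_path=None,
    palette: str = "blue-yellow",
) -> pd.DataFrame:
    """Reorder a matrix for display and optionally write image + TSV.

    ``row_order`` / ``col_order`` must be permutations of the row/column
    positions (or labels, for a DataFrame).  The data are reordered, never
    mutated.  Returns the reordered frame."""
    if isinstance(matrix, BetaMatrix):
        matrix = matrix.values
    frame = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    row_order = list(row_order)
    col_order = list(col_order)
    if len(row_order) != frame.shape[0] or len(col_order) != frame.shape[1]:
        raise ValueError("order length mismatch with matrix shape")

    def _resolve(order, index):
        if all(isinstance(o, (int, np.integer)) for o in order):
            if sorted(order) != list(range(len(index))):
                raise ValueError("order is not a permutation")
            return index[np.asarray(order, dtype=int)]
        if sorted(map(str, order)) != sorted(map(str, index)):
            raise ValueError("order is not a permutation of the labels")
        return pd.Index(order)

    rows = _resolve(row_order, frame.index)
    cols = _resolve(col_order, frame.columns)
    out = frame.loc[rows, cols]
    if tsv_path is not None:
        out.to_csv(tsv_path, sep="\t", float_format="%.10g")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cmap = "YlGnBu" if palette == "blue-yellow" else palette
        fig, ax = plt.subplots(
            figsize=(max(3, out.shape[1] / 25), max(3, out.shape[0] / 25))
        )
        im = ax.imshow(out.to_numpy(dtype=float), aspect="auto", cmap=cmap,
                       vmin=0.0, vmax=1.0, interpolation="nearest")
        fig.colorbar(im, ax=ax, label="average beta")
        ax.set_xlabel("CpG loci")
        ax.set_ylabel("samples")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return out
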