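"""Multi-cell analysis: clustering, embedding, tumor-cell selection.

Cells are compared by the Manhattan (L1) distance between their genome-wide
integer copy-number profiles and agglomerated with Ward's method — the
standard pairing for single-cell copy-number heatmaps.  A 2-D view comes
from classical (eigendecomposition) multidimensional scaling of the same
distance matrix, with an optional iterative metric-stress variant.

Tumor-cell selection here is a deliberately simple recurrence filter: a
cell is kept when enough of its autosomal genome deviates from copy number
2 *and* its altered bins overlap regions recurrently altered across the
aberrant cells.  (It is a plumbing substitute for a full recurrent-event
significance analysis, and is disclosed as such in the configuration.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .binning import DEFAULT_SEX_CHROMS, VariableBinning

logger = logging.getLogger(__name__)


def _complete_matrix(cn_matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop all-NaN (masked) bins; error on cell-inconsistent missingness."""
    M = cn_matrix.to_numpy(dtype=float)
    nan = np.isnan(M)
    partial = nan.any(axis=0) & ~nan.all(axis=0)
    if partial.any():
        raise ValueError(
            f"{int(partial.sum())} bins are missing in some cells but not "
            "others; cells must share a binning and mask")
    return cn_matrix.loc[:, ~nan.all(axis=0)]


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list
    ordered_matrix: pd.DataFrame

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = sch.to_tree(self.linkage)
        labels = list(self.ordered_matrix.index.astype(str))
        labels = sorted(labels)  # leaves indexed by pre-sort order

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return rec(tree, tree.dist) + ";"


def cluster_cells(cn_matrix: pd.DataFrame) -> ClusterResult:
    """Ward-linkage hierarchical clustering on Manhattan CN distances.

    Rows are cells, columns bins.  Cells are sorted by id before computing
    distances so that tie-breaking (and hence leaf order) is deterministic
    and independent of input order; the returned matrix rows follow the
    dendrogram leaf order.
    """
    if len(cn_matrix) < 2:
        raise ValueError("clustering needs >= 2 cells")
    cn_matrix = _complete_matrix(cn_matrix).sort_index(kind="stable")
    D = pdist(cn_matrix.to_numpy(dtype=float), metric="cityblock")
    Z = sch.linkage(D, method="ward")
    order = sch.leaves_list(Z)
    ordered = cn_matrix.iloc[order]
    return ClusterResult(linkage=Z, leaf_order=list(ordered.index),
                         ordered_matrix=ordered)


def cut_clusters(result: ClusterResult, k: int) -> pd.Series:
    """Flat cluster labels from cutting the dendrogram into ``k`` groups."""
    labels = sch.fcluster(result.linkage, k, criterion="maxclust")
    ids = sorted(result.ordered_matrix.index)
    return pd.Series(labels, index=ids, name="cluster")


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Deterministic: eigendecomposition of the double-centered squared
    distances; component signs are fixed so the largest-magnitude loading
    is positive.
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[idx], 0, None)
    coords = v[:, idx] * np.sqrt(w)
    for c in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, c])))
        if coords[j, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords


def mds_embed(cn_matrix: pd.DataFrame, seed: int = 0,
              method: str = "classical") -> pd.DataFrame:
    """2-D embedding of cells from Manhattan CN distances.

    ``method="classical"`` (default) is deterministic; ``method="metric"``
    runs the seeded SMACOF stress optimizer from scikit-learn.
    """
    if len(cn_matrix) < 3:
        raise ValueError("MDS needs >= 3 cells")
    cn_matrix = _complete_matrix(cn_matrix)
    D = squareform(pdist(cn_matrix.to_numpy(dtype=float), metric="cityblock"))
    if method == "classical":
        coords = classical_mds(D)
    elif method == "metric":
        from sklearn.manifold import MDS

        mds = MDS(n_components=2, metric="precomputed", init="random",
                  random_state=seed & 0x7FFFFFFF, normalized_stress="auto")
        coords = mds.fit_transform(D)
    else:
        raise ValueError(f"unknown MDS method {method!r}")
    return pd.DataFrame({"cell": cn_matrix.index, "x": coords[:, 0],
                         "y": coords[:, 1]}).set_index("cell")


def select_tumor_cells(
    cn_matrix: pd.DataFrame,
    bins: VariableBinning,
    min_altered_fraction: float = 0.05,
    recurrence_fraction: float = 0.25,
    sex_chroms=DEFAULT_SEX_CHROMS,
) -> tuple[list, float]:
    """Recurrence-based tumor-cell filter and cellularity estimate.

    A cell is *aberrant* when the fraction of its unmasked autosomal bins
    with CN != 2 exceeds ``min_altered_fraction``.  Bins altered in at least
    ``recurrence_fraction`` of the aberrant cells define the recurrent
    regions; an aberrant cell is retained when any of its altered bins lies
    in a recurrent region.  Cellularity = retained / total cells.
    """
    auto = bins.is_autosome(sex_chroms) & ~bins.mask
    M = cn_matrix.to_numpy(dtype=float)[:, auto]
    altered = np.isfinite(M) & (M != 2)
    frac = altered.mean(axis=1)
    aberrant = frac > min_altered_fraction
    if not aberrant.any():
        warnings.warn("no cell exceeds the altered-fraction threshold")
        return [], 0.0
    recurrent = altered[aberrant].mean(axis=0) >= recurrence_fraction
    keep = aberrant & (altered & recurrent[None, :]).any(axis=1)
    retained = [cid for cid, k in zip(cn_matrix.index, keep) if k]
    return retained, len(retained) / len(cn_matrix)


def plot_heatmap(result: ClusterResult, bins: VariableBinning, path,
                 vmax: float = 6.0) -> None:
    """Save a dendrogram-ordered copy-number heatmap (PNG/SVG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = result.ordered_matrix.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(10, 0.25 * len(M) + 1.5))
    im = ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=0, vmax=vmax,
                   interpolation="nearest")
    ax.set_yticks(range(len(M)))
    ax.set_yticklabels(result.leaf_order, fontsize=6)
    ax.set_xlabel("bin")
    fig.colorbar(im, ax=ax, label="copy number")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
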