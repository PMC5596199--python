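"""Complete-linkage clustering of per-gene fold-change profiles.

Rows of the expression matrix are the genes significant in at least one
mutant contrast; columns are (strain, condition) contrasts; values are log2
fold changes with untested/undefined entries imputed as 0 (absent contrasts
carry no signal).  The dendrogram is cut in two steps: a top-level split into
``top_k`` clusters, after which the largest cluster may be re-cut at a lower
fixed height — the semiautomated two-threshold procedure used to isolate a
strongly responding cluster for motif discovery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


@dataclass
class Dendrogram:
    """A linkage matrix plus the row labels it was built from."""

    linkage: np.ndarray  # scipy (n-1, 4) merge table
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def __post_init__(self):
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage size does not match labels")
        if (np.diff(self.heights) < -1e-9).any():
            raise ValueError("merge heights must be non-decreasing")


@dataclass
class ClusterCutParams:
    top_k: int = 2
    sub_threshold: float | None = 7.0

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.sub_threshold is not None and self.sub_threshold <= 0:
            raise ValueError("sub_threshold must be positive")


def build_expression_matrix(de_results: dict[str, pd.DataFrame],
                            fill_value: float = 0.0) -> pd.DataFrame:
    """Genes significant in >=1 contrast x contrast labels, values log2fc."""
    sig_genes: set[str] = set()
    for df in de_results.values():
        sig_genes |= set(df.index[df["significant"].astype(bool)])
    rows = sorted(sig_genes)
    mat = pd.DataFrame(index=rows, columns=list(de_results), dtype=float)
    for label, df in de_results.items():
        mat[label] = df["log2fc"].reindex(rows)
    return mat.fillna(fill_value)


def complete_linkage(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with inter-cluster distance = max pairwise
    Euclidean distance."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="complete",
                          metric="euclidean")
    return Dendrogram(linkage=Z, labels=list(matrix.index))


def cut_clusters(dendrogram: Dendrogram, params: ClusterCutParams) -> pd.Series:
    """Two-stage cut: ``top_k`` clusters, then re-cut the largest at
    ``sub_threshold``.  Labels are 'C1', 'C2', ... with subclusters 'C2.1'.

    Top-level clusters are numbered by first appearance in the label order,
    so labelling is deterministic for a given dendrogram.
    """
    n = len(dendrogram.labels)
    if params.top_k > n:
        raise ValueError("top_k exceeds the number of leaves")
    top = hierarchy.fcluster(dendrogram.linkage, t=params.top_k,
                             criterion="maxclust")
    # stable renumbering by first occurrence
    remap: dict[int, int] = {}
    for c in top:
        if c not in remap:
            remap[c] = len(remap) + 1
    labels = np.array([f"C{remap[c]}" for c in top], dtype=object)
    if params.sub_threshold is not None and params.top_k < n:
        sizes = pd.Series(labels).value_counts()
        largest = sizes.idxmax()
        sub = hierarchy.fcluster(dendrogram.linkage, t=params.sub_threshold,
                                 criterion="distance")
        mask = labels == largest
        sub_remap: dict[int, int] = {}
        for c in sub[mask]:
            if c not in sub_remap:
                sub_remap[c] = len(sub_remap) + 1
        if len(sub_remap) > 1:
            labels[mask] = [f"{largest}.{sub_remap[c]}" for c in sub[mask]]
    return pd.Series(labels, index=dendrogram.labels, name="cluster")


def cut_at_height(dendrogram: Dendrogram, height: float) -> pd.Series:
    """Flat clusters from a straight distance cut of the dendrogram."""
    flat = hierarchy.fcluster(dendrogram.linkage, t=height, criterion="distance")
    remap: dict[int, int] = {}
    for c in flat:
        if c not in remap:
            remap[c] = len(remap) + 1
    return pd.Series([f"C{remap[c]}" for c in flat], index=dendrogram.labels,
                     name="cluster")


def cluster_mean_profiles(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Mean profile per cluster (rows = clusters, columns as in the matrix)."""
    return matrix.groupby(labels).mean()


def heatmap_export(matrix: pd.DataFrame, dendrogram: Dendrogram,
                   labels: pd.Series, path: str | os.PathLike,
                   image_path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Rows in dendrogram leaf order with their cluster labels; numeric values
    unchanged.  Optionally renders a simple heat map image."""
    order = dendrogram.leaf_order
    out = matrix.loc[order].copy()
    out.insert(0, "cluster", labels.loc[order])
    out.to_csv(path, sep="\t")
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, max(3, len(out) * 0.02)))
        vals = matrix.loc[order].to_numpy(dtype=float)
        vmax = np.nanmax(np.abs(vals)) or 1.0
        ax.imshow(vals, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                  interpolation="nearest")
        ax.set_xticks(range(len(matrix.columns)))
        ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        ax.set_title("log2 fold change, dendrogram leaf order")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return out
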