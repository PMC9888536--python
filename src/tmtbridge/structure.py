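"""Z-scoring, hierarchical clustering of expression patterns, and sample PCA.

Protein abundances are standardized per row (Z-scores over the biological
samples, n-1 denominator) so clustering compares expression *patterns*, not
magnitudes; agglomerative clustering on Euclidean row distances is then cut
into k groups, mirroring the k-cluster heatmap view of the study design this
package targets.  The linkage method is a documented choice (complete by
default, the common default of the heatmap tooling family) and is
config-switchable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .core_io import NormalizedMatrix, StudyDesign

__all__ = ["ClusterAssignment", "zscore_rows", "hcluster_cut", "pca_samples", "heatmap_export"]


def zscore_rows(data: pd.DataFrame, design: StudyDesign | None = None,
                over: str = "samples"):
    """Standardize each row to mean 0, sd 1 (sample sd, n-1 denominator).

    ``over='samples'`` standardizes across the biological sample columns
    (bridges excluded when a design is given); ``over='condition-means'``
    first averages replicates within each condition.  Constant rows become
    all-zero and are reported in the returned warning list.

    Returns ``(zmat, constant_row_ids)``.
    """
    if isinstance(data, NormalizedMatrix):
        if design is None:
            design = data.design
        data = data.data
    if over == "condition-means":
        if design is None:
            raise ValueError("condition-means Z-scores require a design")
        data = pd.DataFrame({c: data[design.samples_of(c)].mean(axis=1)
                             for c in design.conditions})
    elif over == "samples":
        if design is not None:
            data = data.loc[:, design.merged_columns(bridges="none")]
    else:
        raise ValueError("over must be 'samples' or 'condition-means'")
    if data.shape[1] < 2:
        raise ValueError("Z-scores need >= 2 columns")
    mu = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    constant = sd.index[sd == 0]
    sd = sd.replace(0.0, 1.0)
    z = data.sub(mu, axis=0).div(sd, axis=0)
    z.loc[constant] = 0.0
    return z, list(constant)


@dataclass
class ClusterAssignment:
    """k-cluster cut of an agglomerative merge tree.

    ``labels`` maps protein id -> cluster index in 1..k, indices ordered by
    decreasing cluster size; ``linkage`` is the scipy merge tree (heights
    included) over rows sorted lexicographically by protein id, and
    ``leaf_order`` the dendrogram leaf order of those ids.
    """

    labels: pd.Series
    linkage: np.ndarray
    k: int
    leaf_order: list

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def hcluster_cut(zmat: pd.DataFrame, k: int = 9, method: str = "complete") -> ClusterAssignment:
    """Euclidean agglomerative clustering of rows, cut into exactly k groups.

    Rows are processed in lexicographic protein-id order so the partition is
    deterministic and independent of input row order.  Cluster indices are
    relabeled by decreasing size (ties broken by first appearance in the
    sorted id order).
    """
    if k > zmat.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows ({zmat.shape[0]})")
    if k < 1:
        raise ValueError("k must be >= 1")
    zmat = zmat.sort_index()
    Z = hierarchy.linkage(pdist(zmat.to_numpy(), metric="euclidean"), method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=zmat.index, name="cluster")
    # order clusters by decreasing size, stable on first appearance
    counts = labels.value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], int(np.argmax(raw == c))))
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = labels.map(remap)
    leaves = [zmat.index[i] for i in hierarchy.leaves_list(Z)]
    return ClusterAssignment(labels=labels, linkage=Z, k=k, leaf_order=leaves)


def pca_samples(norm: NormalizedMatrix, include_bridges: bool = False):
    """PCA of the samples (observations) in protein space (variables).

    Columns (proteins) are mean-centered.  Returns ``(scores,
    explained_fractions)`` where scores is a samples x components DataFrame
    and the explained-variance fractions sum to 1.
    """
    cols = (norm.design.merged_columns(bridges="all") if include_bridges
            else norm.design.merged_columns(bridges="none"))
    X = norm.data.loc[:, cols].to_numpy().T  # samples x proteins
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    frac = pca.explained_variance_ratio_
    frac = frac / frac.sum()  # fractions of the retained spectrum sum to 1
    score_df = pd.DataFrame(
        scores, index=pd.Index(cols, name="sample"),
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return score_df, frac


def heatmap_export(zmat: pd.DataFrame, assignment: ClusterAssignment,
                   design: StudyDesign, tsv_path, fig_path=None):
    """Write the clustered Z-score matrix ordered by dendrogram leaves.

    The TSV mirror (protein, cluster, then one column per sample) is the
    diffable source of truth for the rendered heatmap; the figure is optional
    plumbing.  Returns the ordered DataFrame that was written.
    """
    ordered = zmat.loc[assignment.leaf_order].copy()
    ordered.insert(0, "cluster", assignment.labels.loc[assignment.leaf_order])
    ordered.to_csv(tsv_path, sep="\t", float_format="%.6g")
    if fig_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 10))
        body = ordered.drop(columns="cluster")
        im = ax.imshow(body.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-2.5, vmax=2.5, interpolation="nearest")
        bounds = np.flatnonzero(np.diff(ordered["cluster"].to_numpy()) != 0) + 0.5
        for y in bounds:
            ax.axhline(y, color="black", lw=0.5)
        ax.set_xticks(range(body.shape[1]))
        ax.set_xticklabels(body.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        ax.set_ylabel(f"{body.shape[0]} proteins in {assignment.k} clusters")
        fig.colorbar(im, ax=ax, label="Z-score")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return ordered
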