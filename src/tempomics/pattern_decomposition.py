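"""Clustering and PCA of normalized mean trajectories.

Hierarchical clustering uses Euclidean distance with Ward's method in the
``ward.D2`` convention (pairwise distances are not pre-squared), the default
of modern implementations. The tree is cut to a requested number of
clusters; ids are renumbered 1..K in dendrogram leaf order so cluster 1 is
the leftmost branch.

Each cluster mean trajectory is labelled on three axes:

* amplitude — ``large`` when max |Ybar| > 2.5, ``small`` when in (1.5, 2.5],
  ``not_clear`` below 1.5 (normalized units);
* kinetics — ``transient`` when |Ybar| later falls to <= 50% of its global
  extremum, else ``sustained``; ``not_clear`` amplitude implies ``not_clear``
  kinetics;
* direction — the sign of the global extremum.

PCA is computed by SVD of the column-centred (per time point, across
molecules) matrix without variance scaling. Scores are row projections;
the factor loading of a component at a time point is the Pearson
correlation between the component's scores and that time-point column, so
loadings live on a [-1, 1] scale. Signs are fixed so PC1 (the amplitude
component) has a positive loading at the time point nearest 90 min and PC2
(the rate component) a positive loading at the earliest post-ingestion time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

AMPLITUDE_LARGE = 2.5
AMPLITUDE_SMALL = 1.5
TRANSIENCE_FRACTION = 0.5


@dataclass
class ClusterResult:
    linkage: np.ndarray            # scipy linkage matrix, Euclidean-Ward heights
    assignment: pd.Series          # molecule -> cluster id (1..K)
    labels: pd.DataFrame           # cluster, amplitude, kinetics, direction
    cluster_means: pd.DataFrame    # cluster x time mean trajectories

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max())


@dataclass
class PCAResult:
    scores: pd.DataFrame                 # molecule x PC
    loadings: pd.DataFrame               # time x PC, correlation scale
    explained_variance_ratio: np.ndarray


def hierarchical_cluster(M: pd.DataFrame, k: int) -> ClusterResult:
    """Ward/Euclidean clustering of molecule trajectories, cut to k clusters.

    ``M`` is molecules x times with no missing entries (incomplete molecules
    are excluded upstream). Cluster ids follow dendrogram leaf order.
    """
    values = np.asarray(M, dtype=float)
    if np.isnan(values).any():
        bad = list(M.index[np.isnan(values).any(axis=1)])
        raise ValueError(f"missing entries in trajectories of {bad}")
    n = values.shape[0]
    if k > n:
        raise ValueError(f"requested {k} clusters for {n} molecules")
    Z = hierarchy.linkage(values, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    # renumber clusters by first appearance along the dendrogram leaves
    leaf_order = hierarchy.leaves_list(Z)
    relabel: dict[int, int] = {}
    for leaf in leaf_order:
        relabel.setdefault(raw[leaf], len(relabel) + 1)
    ids = np.array([relabel[c] for c in raw])
    assignment = pd.Series(ids, index=M.index, name="cluster")

    times = list(M.columns)
    means = {
        c: values[ids == c].mean(axis=0) for c in range(1, int(ids.max()) + 1)
    }
    cluster_means = pd.DataFrame.from_dict(means, orient="index", columns=times)
    labels = pd.DataFrame(
        [
            dict(cluster=c, **dict(zip(("amplitude", "kinetics", "direction"),
                                       label_cluster(cluster_means.loc[c].to_numpy()))))
            for c in cluster_means.index
        ]
    )
    return ClusterResult(Z, assignment, labels, cluster_means)


def label_cluster(trajectory: np.ndarray) -> tuple[str, str, str]:
    """(amplitude, kinetics, direction) labels for one mean trajectory."""
    traj = np.asarray(trajectory, dtype=float)
    i_ext = int(np.argmax(np.abs(traj)))
    extremum = traj[i_ext]
    peak = abs(extremum)

    if peak > AMPLITUDE_LARGE:
        amplitude = "large"
    elif peak > AMPLITUDE_SMALL:
        amplitude = "small"
    else:
        return ("not_clear", "not_clear", "increase" if extremum >= 0 else "decrease")

    after = np.abs(traj[i_ext + 1 :])
    transient = after.size > 0 and bool(np.any(after <= TRANSIENCE_FRACTION * peak))
    kinetics = "transient" if transient else "sustained"
    direction = "increase" if extremum > 0 else "decrease"
    return (amplitude, kinetics, direction)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a merge tree as a Newick string with branch lengths.

    Branch lengths are the difference between a node's merge height and its
    child's, so leaf-to-root distances reproduce the dendrogram heights.
    """
    n = len(labels)

    def subtree(idx: int) -> tuple[str, float]:
        if idx < n:
            return labels[idx], 0.0
        left, right, height, _ = Z[idx - n]
        parts = []
        for child in (int(left), int(right)):
            text, child_height = subtree(child)
            parts.append(f"{text}:{height - child_height:g}")
        return "(" + ",".join(parts) + ")", height

    text, _ = subtree(len(Z) + n - 1)
    return text + ";"


def pca_decompose(M: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """SVD-based PCA of molecule x time trajectories.

    Columns (time points) are mean-centred across molecules; no variance
    scaling. A zero-variance column yields an undefined (NaN) loading for
    that time point.
    """
    values = np.asarray(M, dtype=float)
    n_mol, n_t = values.shape
    if n_mol < 2 or n_t < 2:
        raise ValueError("PCA needs at least 2 molecules and 2 time points")
    if np.isnan(values).any():
        raise ValueError("missing entries in the PCA input matrix")

    centred = values - values.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    scores = U * s  # row projections
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)

    n_pc = len(s) if n_components is None else min(n_components, len(s))
    pc_names = [f"PC{i + 1}" for i in range(n_pc)]
    scores = scores[:, :n_pc]

    # factor loading = correlation(score column, time column)
    col_sd = centred.std(axis=0)
    score_sd = scores.std(axis=0)
    loadings = np.full((n_t, n_pc), np.nan)
    for a in range(n_pc):
        if score_sd[a] == 0:
            continue
        cov = centred.T @ (scores[:, a] - scores[:, a].mean()) / n_mol
        with np.errstate(invalid="ignore", divide="ignore"):
            load = cov / (col_sd * score_sd[a])
        load[col_sd == 0] = np.nan
        loadings[:, a] = load

    # sign conventions tied to the physiology of the components
    times = np.asarray(M.columns, dtype=float)
    if n_pc >= 1:
        anchor = int(np.argmin(np.abs(times - 90.0)))
        if not np.isnan(loadings[anchor, 0]) and loadings[anchor, 0] < 0:
            scores[:, 0] *= -1
            loadings[:, 0] *= -1
    if n_pc >= 2:
        post = np.flatnonzero(times > 0)
        anchor = int(post[0]) if post.size else 0
        if not np.isnan(loadings[anchor, 1]) and loadings[anchor, 1] < 0:
            scores[:, 1] *= -1
            loadings[:, 1] *= -1

    return PCAResult(
        scores=pd.DataFrame(scores, index=M.index, columns=pc_names),
        loadings=pd.DataFrame(loadings, index=M.columns, columns=pc_names),
        explained_variance_ratio=evr[:n_pc],
    )
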