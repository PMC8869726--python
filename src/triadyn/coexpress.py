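"""Co-expression clustering of temporal profiles.

Genes are represented by their replicate-mean FPKM across time points,
z-scored per gene.  k-means under Pearson-correlation distance is run
as Euclidean k-means on the z-scored rows: for rows of length T with
mean 0 and unit variance, squared Euclidean distance equals
2T(1 - r), so the two objectives share their minimizers.  The number
of clusters is chosen by the overall (mean) silhouette coefficient
computed with the correlation distance 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

#: default k-means restarts
N_INIT = 25


def zscore_profiles(timepoint_means: pd.DataFrame, genes=None):
    """Per-gene z-scored temporal profiles.

    Constant profiles cannot be z-scored (their correlation with
    anything is undefined); they are dropped and reported.

    Returns
    -------
    profiles : DataFrame of z-scored rows (mean 0, unit variance).
    excluded : list of gene ids dropped as constant.
    """
    prof = timepoint_means if genes is None else timepoint_means.loc[list(genes)]
    arr = prof.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    constant = sd == 0
    z = (arr[~constant] - arr[~constant].mean(axis=1, keepdims=True)) / sd[~constant, None]
    out = pd.DataFrame(z, index=prof.index[~constant], columns=prof.columns)
    return out, list(prof.index[constant])


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> "C1".."Ck"
    cluster_means: pd.DataFrame  # cluster x time point mean z-profile
    k: int
    inertia: float
    silhouette: float


def _check_zscored(profiles: pd.DataFrame):
    arr = profiles.to_numpy(dtype=float)
    if arr.shape[0] == 0:
        raise ValueError("no profiles to cluster")
    sd = arr.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant profile reached clustering; z-score first")
    return arr


def kmeans_correlation(profiles: pd.DataFrame, k: int, seed: int = 0,
                       n_init: int = N_INIT) -> ClusterAssignment:
    """k-means under correlation distance on z-scored profiles.

    k-means++ initialization, best of ``n_init`` restarts by
    within-cluster sum of squares; deterministic given the seed.
    """
    arr = _check_zscored(profiles)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(profiles) < k:
        raise ValueError(f"{len(profiles)} profiles cannot form {k} clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed).fit(arr)
    labels = pd.Series([f"C{c + 1}" for c in km.labels_], index=profiles.index,
                       name="cluster")
    means = pd.DataFrame(km.cluster_centers_, columns=profiles.columns,
                         index=[f"C{c + 1}" for c in range(k)])
    sil = silhouette_overall(profiles, labels)
    return ClusterAssignment(labels=labels, cluster_means=means, k=k,
                             inertia=float(km.inertia_), silhouette=sil)


def silhouette_samples_correlation(profiles: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Per-gene silhouette under correlation distance (1 - Pearson r).

    Genes in singleton clusters score 0; if both the mean intra- and
    nearest-other-cluster distances are 0 the score is 0 by convention.
    """
    arr = np.asarray(profiles, dtype=float)
    lab = np.asarray(labels.loc[profiles.index])
    uniq = pd.unique(lab)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    dist = squareform(pdist(arr, metric="correlation"))
    n = len(arr)
    scores = np.zeros(n)
    masks = {c: lab == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(n):
        own = lab[i]
        if sizes[own] == 1:
            scores[i] = 0.0
            continue
        a = dist[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(dist[i, masks[c]].mean() for c in uniq if c != own)
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return pd.Series(scores, index=profiles.index, name="silhouette")


def silhouette_overall(profiles: pd.DataFrame, labels: pd.Series) -> float:
    """Overall silhouette: the mean per-gene score."""
    return float(silhouette_samples_correlation(profiles, labels).mean())


def select_k(profiles: pd.DataFrame, k_range=range(2, 16), seed: int = 0,
             n_init: int = N_INIT):
    """Choose k by the highest overall silhouette.

    Runs k-means for each k in ``k_range``; ties break toward the
    smaller k.  Returns (best k, silhouette-vs-k table, assignment at
    the best k).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] > len(profiles) - 1:
        raise ValueError("k range must lie within [2, n_profiles - 1]")
    best = None
    rows = []
    for k in ks:
        assignment = kmeans_correlation(profiles, k, seed=seed, n_init=n_init)
        rows.append({"k": k, "silhouette": assignment.silhouette})
        if best is None or assignment.silhouette > best.silhouette:
            best = assignment
    table = pd.DataFrame(rows)
    return best.k, table, best
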