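"""FPKM normalization, expressed-gene filtering and sample-level QC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix


def fpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total[s]) where
    total[s] is the summed counts of sample s.
    """
    if counts.unit != "counts":
        raise ValueError("input matrix must be in counts")
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise KeyError(f"gene without length: {missing[0]!r}")
    glen = lengths.loc[counts.gene_ids].astype(float)
    if (glen <= 0).any():
        bad = glen.index[glen <= 0][0]
        raise ValueError(f"gene {bad!r} has non-positive length")
    totals = counts.values.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    vals = counts.values.mul(1e9).div(glen, axis=0).div(totals, axis=1)
    return ExpressionMatrix(values=vals, samples=counts.samples.copy(), unit="fpkm")


@dataclass
class ExpressedSets:
    """Expressed-gene sets: one per time point and the overall union."""

    per_timepoint: dict
    overall: set

    def counts(self) -> pd.Series:
        out = {tp: len(s) for tp, s in self.per_timepoint.items()}
        out["overall"] = len(self.overall)
        return pd.Series(out, name="n_expressed")


def expressed_genes(fpkm_matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressedSets:
    """Expressed-gene sets under the strict FPKM > threshold rule.

    A gene is expressed at a time point when its replicate-mean FPKM
    there exceeds the threshold (strictly), and expressed overall when
    expressed at one or more time points.
    """
    if fpkm_matrix.unit != "fpkm":
        raise ValueError("expressed_genes expects FPKM values")
    means = fpkm_matrix.timepoint_means()
    per_tp = {tp: set(means.index[means[tp] > threshold]) for tp in means.columns}
    overall = set().union(*per_tp.values()) if per_tp else set()
    return ExpressedSets(per_timepoint=per_tp, overall=overall)


@dataclass
class QCResult:
    """Sample QC: Spearman correlations, dendrogram merges, PCA."""

    scc: pd.DataFrame
    dendrogram: np.ndarray  # scipy linkage matrix, average linkage on 1 - SCC
    pca_coords: pd.DataFrame  # samples x (PC1, PC2)
    explained_variance: np.ndarray  # fractions for PC1, PC2


def sample_qc(fpkm_matrix: ExpressionMatrix) -> QCResult:
    """Replicate-quality summaries used to vet a time-course experiment.

    Spearman correlation between all sample pairs (average ranks for
    ties), average-linkage hierarchical clustering on 1 - SCC, and PCA
    of log2(FPKM + 1) with genes as features.
    """
    vals = fpkm_matrix.values
    if vals.shape[1] < 2:
        raise ValueError("sample QC needs at least two samples")
    rho = stats.spearmanr(vals.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    scc = pd.DataFrame(rho, index=vals.columns, columns=vals.columns)

    dist = 1.0 - scc.to_numpy()
    np.fill_diagonal(dist, 0.0)
    merges = linkage(squareform(dist, checks=False), method="average")

    logged = np.log2(vals.to_numpy().T + 1.0)
    pca = PCA(n_components=min(2, logged.shape[0] - 1, logged.shape[1]),
              svd_solver="full")
    coords = pca.fit_transform(logged)
    pca_coords = pd.DataFrame(
        coords[:, :2],
        index=vals.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])][:2],
    )
    return QCResult(
        scc=scc,
        dendrogram=merges,
        pca_coords=pca_coords,
        explained_variance=pca.explained_variance_ratio_[:2],
    )
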