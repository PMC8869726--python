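"""Negative-binomial differential expression between adjacent time points.

A self-contained, calibration-tested stand-in for the packaged NB tools
usually applied to such designs.  Counts are normalized by
median-of-ratios size factors; gene-wise dispersions are estimated by a
bias-corrected method of moments and pooled through a robust
mean-dispersion trend alpha(mu) = a0 + a1/mu fitted across genes (the
information sharing that makes 3-versus-3 designs testable); each gene
is then scored with a score-type statistic

    z = (m2 - m1) / sqrt((1/n1 + 1/n2) (mu0 + alpha(mu0) mu0^2))

where m1, m2 are group means of normalized counts and mu0 their pooled
mean, with a two-sided normal reference.  The fold change is reported
as log2((m2 + c)/(m1 + c)) with pseudocount c.  A gene is a DEG when
its Benjamini-Hochberg adjusted p is below 0.05 and |log2FC| >= 1
(thresholds configurable), with the earlier time point as control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

#: pseudocount on normalized group means for fold changes
PSEUDOCOUNT = 0.5
#: floor on the trended dispersion
ALPHA_MIN = 1e-4


def size_factors(counts) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Per-gene geometric means are computed over samples (genes with any
    zero are excluded); the size factor of a sample is the median over
    genes of count/geomean.
    """
    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    arr = values.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with positive counts in all samples")
    loggeo = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - loggeo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=values.columns, name="size_factor")


def _dispersion_trend(mp: np.ndarray, vp: np.ndarray, n_total: int,
                      alpha_min: float = ALPHA_MIN):
    """Fit alpha(mu) = a0 + a1/mu to bias-corrected moment estimates.

    The gene-wise estimator divides the excess variance by an unbiased
    estimate of mu^2 (mp^2 - vp/n); the trend is fitted by trimmed
    least squares so dispersion outliers do not drag it.
    """
    denom = np.maximum(mp**2 - vp / n_total, 1e-12)
    w = (vp - mp) / denom
    ok = mp > 1.0
    if ok.sum() < 10:
        a0 = float(np.median(w[ok])) if ok.any() else alpha_min
        return max(a0, alpha_min), 0.0
    x = 1.0 / mp[ok]
    y = w[ok]
    keep = np.ones(ok.sum(), dtype=bool)
    coef = np.array([alpha_min, 0.0])
    for _ in range(5):
        A = np.column_stack([np.ones(keep.sum()), x[keep]])
        coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        resid = y - (coef[0] + coef[1] * x)
        s = np.median(np.abs(resid)) * 1.4826 + 1e-12
        keep = np.abs(resid) < 3.5 * s
    return float(coef[0]), float(coef[1])


def nb_test(counts: ExpressionMatrix, contrast, factors: pd.Series | None = None,
            pseudocount: float = PSEUDOCOUNT, alpha_min: float = ALPHA_MIN,
            genes=None) -> pd.DataFrame:
    """Per-gene fold change and raw p for one adjacent-time-point contrast.

    Parameters
    ----------
    contrast : (earlier, later) pair of time-point labels; the earlier
        time point is the control.
    factors : precomputed size factors (computed on the full matrix if
        omitted).
    genes : optional subset of gene ids to test.

    Returns
    -------
    DataFrame indexed by gene id with columns ``log2fc``, ``p_raw``,
    ``base_mean`` and ``dispersion``.  All-zero genes get (0, 1).
    """
    t1, t2 = contrast
    s1 = counts.samples_at(t1)
    s2 = counts.samples_at(t2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"contrast {t1}->{t2}: each group needs >= 2 replicates")
    if factors is None:
        factors = size_factors(counts)
    values = counts.values if genes is None else counts.values.loc[list(genes)]
    y1 = values[s1].to_numpy(float) / factors.loc[s1].to_numpy()
    y2 = values[s2].to_numpy(float) / factors.loc[s2].to_numpy()
    n1, n2 = y1.shape[1], y2.shape[1]

    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)
    vp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mp = (n1 * m1 + n2 * m2) / (n1 + n2)

    a0, a1 = _dispersion_trend(mp, vp, n1 + n2, alpha_min)
    alpha = np.maximum(alpha_min, a0 + a1 / np.maximum(mp, 1e-12))

    var0 = (1.0 / n1 + 1.0 / n2) * (mp + alpha * mp**2)
    nonzero = mp > 0
    z = np.zeros(len(mp))
    z[nonzero] = (m2[nonzero] - m1[nonzero]) / np.sqrt(var0[nonzero])
    p = np.ones(len(mp))
    p[nonzero] = 2.0 * stats.norm.sf(np.abs(z[nonzero]))

    log2fc = np.zeros(len(mp))
    log2fc[nonzero] = np.log2((m2[nonzero] + pseudocount) / (m1[nonzero] + pseudocount))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p, "base_mean": mp, "dispersion": alpha},
        index=values.index,
    )


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(results: pd.DataFrame, p_threshold: float = 0.05,
              lfc_threshold: float = 1.0):
    """Flag DEGs and summarise counts per contrast.

    ``results`` is a tidy frame with columns gene_id, contrast, log2fc,
    p_adj.  A gene is a DEG under strict p_adj < p_threshold and
    |log2fc| >= lfc_threshold.  Returns the flagged frame and a summary
    with per-contrast DEG counts plus the union count.
    """
    out = results.copy()
    out["is_deg"] = (out["p_adj"] < p_threshold) & (out["log2fc"].abs() >= lfc_threshold)
    per_contrast = out[out["is_deg"]].groupby("contrast", sort=False)["gene_id"].nunique()
    per_contrast = per_contrast.reindex(pd.unique(out["contrast"]), fill_value=0)
    summary = per_contrast.to_frame("n_degs")
    summary.loc["union"] = out.loc[out["is_deg"], "gene_id"].nunique()
    return out, summary


def run_de(counts: ExpressionMatrix, expressed_per_timepoint: dict | None = None,
           p_threshold: float = 0.05, lfc_threshold: float = 1.0,
           pseudocount: float = PSEUDOCOUNT, alpha_min: float = ALPHA_MIN):
    """Test all adjacent time-point contrasts and call DEGs.

    When per-time-point expressed-gene sets are supplied, a gene is
    tested in a contrast only if expressed at one of its two time
    points; BH adjustment runs per contrast over the tested genes.
    Returns (tidy results frame, summary frame).
    """
    tps = counts.timepoints
    if len(tps) < 2:
        raise ValueError("need at least two time points")
    factors = size_factors(counts)
    frames = []
    for t1, t2 in zip(tps[:-1], tps[1:]):
        genes = None
        if expressed_per_timepoint is not None:
            keep = expressed_per_timepoint.get(t1, set()) | expressed_per_timepoint.get(t2, set())
            genes = [g for g in counts.gene_ids if g in keep]
            if not genes:
                continue
        res = nb_test(counts, (t1, t2), factors, pseudocount, alpha_min, genes=genes)
        res = res.reset_index().rename(columns={"index": "gene_id"})
        res["contrast"] = f"{t1}->{t2}"
        res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
        frames.append(res)
    tidy = pd.concat(frames, ignore_index=True)
    tidy = tidy[["gene_id", "contrast", "log2fc", "p_raw", "p_adj", "base_mean", "dispersion"]]
    return call_degs(tidy, p_threshold, lfc_threshold)
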