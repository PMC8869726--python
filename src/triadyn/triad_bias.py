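"""Homoeolog expression-bias classification of subgenome triads.

A triad is the set of three homoeologous genes, one per subgenome (A, B,
D) of hexaploid wheat.  At each time point the triad's relative
expression contributions (fA, fB, fD), computed from replicate-mean
FPKM, place it on the 2-simplex; the triad is assigned the bias category
whose ideal centroid is nearest in Euclidean distance:

=============  ===================
category       centroid (fA,fB,fD)
=============  ===================
Balance        (1/3, 1/3, 1/3)
A dominant     (1, 0, 0)
B dominant     (0, 1, 0)
D dominant     (0, 0, 1)
A suppressed   (0, 1/2, 1/2)
B suppressed   (1/2, 0, 1/2)
D suppressed   (1/2, 1/2, 0)
=============  ===================

Triads whose summed replicate-mean FPKM is <= 1 at a time point are
assigned the extra "Low" (not expressed) category there and carry no
fractions.  Ties in the nearest-centroid rule are broken conservatively:
Balance first, then the suppressed, then the dominant categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

#: tie-break priority order of the seven expressed categories
CATEGORIES: tuple[str, ...] = (
    "Balance",
    "A suppressed",
    "B suppressed",
    "D suppressed",
    "A dominant",
    "B dominant",
    "D dominant",
)

LOW = "Low"

#: all assignable states, Low last
ALL_CATEGORIES: tuple[str, ...] = CATEGORIES + (LOW,)

CENTROIDS: dict[str, np.ndarray] = {
    "Balance": np.array([1 / 3, 1 / 3, 1 / 3]),
    "A suppressed": np.array([0.0, 0.5, 0.5]),
    "B suppressed": np.array([0.5, 0.0, 0.5]),
    "D suppressed": np.array([0.5, 0.5, 0.0]),
    "A dominant": np.array([1.0, 0.0, 0.0]),
    "B dominant": np.array([0.0, 1.0, 0.0]),
    "D dominant": np.array([0.0, 0.0, 1.0]),
}

_CENTROID_MATRIX = np.vstack([CENTROIDS[c] for c in CATEGORIES])

#: default summed-FPKM threshold separating expressed triads from Low
EXPRESSED_THRESHOLD = 1.0


def relative_contributions(fpkm_a, fpkm_b, fpkm_d):
    """Normalise three homoeolog FPKM values to fractions summing to 1.

    Accepts scalars or aligned arrays; raises if any triple sums to 0
    (callers must gate by the Low rule first).
    """
    a = np.asarray(fpkm_a, dtype=float)
    b = np.asarray(fpkm_b, dtype=float)
    d = np.asarray(fpkm_d, dtype=float)
    total = a + b + d
    if np.any(total <= 0):
        raise ValueError("triad with non-positive total expression; gate by the Low rule first")
    return a / total, b / total, d / total


def classify_fractions(fractions: np.ndarray, atol: float = 1e-6):
    """Vectorised nearest-centroid classification.

    Parameters
    ----------
    fractions : (n, 3) array on the simplex.

    Returns
    -------
    categories : (n,) object array of category names
    distances : (n,) Euclidean distances to the chosen centroid
    """
    fr = np.atleast_2d(np.asarray(fractions, dtype=float))
    if fr.shape[1] != 3:
        raise ValueError("fractions must have three components")
    if np.any(np.abs(fr.sum(axis=1) - 1.0) > atol) or np.any(fr < -atol):
        raise ValueError("fractions must lie on the simplex (sum to 1, non-negative)")
    # distances to the 7 centroids; argmin takes the first minimum, and
    # the centroid rows are already in tie-break priority order
    d2 = ((fr[:, None, :] - _CENTROID_MATRIX[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    cats = np.array(CATEGORIES, dtype=object)[idx]
    dist = np.sqrt(d2[np.arange(len(fr)), idx])
    return cats, dist


def classify_triad(fractions, atol: float = 1e-6):
    """Classify one fraction triple; returns ``(category, distance)``."""
    cats, dist = classify_fractions(np.asarray(fractions, dtype=float)[None, :], atol=atol)
    return str(cats[0]), float(dist[0])


def ternary_coordinates(fractions):
    """Barycentric -> Cartesian map for ternary plotting.

    A sits at the origin, B at (1, 0) and D at (1/2, sqrt(3)/2), so
    x = fB + fD/2 and y = (sqrt(3)/2) fD.  Accepts an (n, 3) array or a
    single triple; invertible on the simplex.
    """
    fr = np.atleast_2d(np.asarray(fractions, dtype=float))
    if np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-6) or np.any(fr < -1e-9):
        raise ValueError("fractions must lie on the simplex")
    x = fr[:, 1] + fr[:, 2] / 2.0
    y = (np.sqrt(3) / 2.0) * fr[:, 2]
    out = np.column_stack([x, y])
    return out[0] if np.ndim(fractions) == 1 else out


def classify_all(
    fpkm: ExpressionMatrix,
    triads: pd.DataFrame,
    threshold: float = EXPRESSED_THRESHOLD,
) -> pd.DataFrame:
    """Classify every triad at every time point.

    Parameters
    ----------
    fpkm : ExpressionMatrix in FPKM units.
    triads : DataFrame indexed by triad id with columns
        ``gene_A``, ``gene_B``, ``gene_D``.
    threshold : summed replicate-mean FPKM at or below which a triad is
        Low at that time point.

    Returns
    -------
    DataFrame with one row per triad x time point: fA, fB, fD (NaN for
    Low), category, distance, total_fpkm.
    """
    if fpkm.unit != "fpkm":
        raise ValueError("classify_all expects FPKM values")
    for col in ("gene_A", "gene_B", "gene_D"):
        missing = set(triads[col]) - set(fpkm.gene_ids)
        if missing:
            bad = triads.index[triads[col].isin(missing)][0]
            raise KeyError(f"triad {bad!r}: member gene missing from expression matrix")

    means = fpkm.timepoint_means()
    tps = list(means.columns)
    a = means.loc[triads["gene_A"]].to_numpy()
    b = means.loc[triads["gene_B"]].to_numpy()
    d = means.loc[triads["gene_D"]].to_numpy()
    total = a + b + d

    rows = []
    for j, tp in enumerate(tps):
        tot = total[:, j]
        low = tot <= threshold
        fa = np.full(len(triads), np.nan)
        fb = np.full(len(triads), np.nan)
        fd = np.full(len(triads), np.nan)
        cat = np.full(len(triads), LOW, dtype=object)
        dist = np.full(len(triads), np.nan)
        if (~low).any():
            fa[~low] = a[~low, j] / tot[~low]
            fb[~low] = b[~low, j] / tot[~low]
            fd[~low] = d[~low, j] / tot[~low]
            cats, dd = classify_fractions(np.column_stack([fa[~low], fb[~low], fd[~low]]))
            cat[~low] = cats
            dist[~low] = dd
        rows.append(
            pd.DataFrame(
                {
                    "triad_id": triads.index,
                    "timepoint": tp,
                    "fA": fa,
                    "fB": fb,
                    "fD": fd,
                    "category": cat,
                    "distance": dist,
                    "total_fpkm": tot,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def category_proportions(assignments: pd.DataFrame, include_low: bool = True) -> pd.DataFrame:
    """Per-time-point category proportions (time points x categories).

    With ``include_low=False``, Low triads are dropped before
    normalising, giving proportions among expressed triads only.
    """
    df = assignments if include_low else assignments[assignments["category"] != LOW]
    cats = ALL_CATEGORIES if include_low else CATEGORIES
    tab = (
        df.groupby(["timepoint", "category"], sort=False).size().unstack(fill_value=0)
    )
    tab = tab.reindex(columns=list(cats), fill_value=0)
    from .containers import timepoint_order

    tab = tab.reindex(timepoint_order(tab.index))
    return tab.div(tab.sum(axis=1), axis=0)


def transitions(assignments: pd.DataFrame):
    """Category transition tables between adjacent time points.

    Returns
    -------
    tables : dict mapping (t, t_next) -> 8x8 count DataFrame whose rows
        are the category at t and columns the category at t_next.
    stability : DataFrame with per-category adjacent-step retention
        (fraction of triads in the category at t still in it at t+1,
        pooled over all adjacent pairs) and full-series stability
        (fraction of triads ever in the category that hold it at every
        time point).
    """
    from .containers import timepoint_order

    tps = timepoint_order(assignments["timepoint"].unique())
    wide = assignments.pivot(index="triad_id", columns="timepoint", values="category")
    if wide.isna().any().any():
        raise ValueError("assignments do not cover identical triad sets at all time points")
    wide = wide[tps]

    cats = list(ALL_CATEGORIES)
    tables = {}
    retained = {c: 0 for c in cats}
    seen = {c: 0 for c in cats}
    for t1, t2 in zip(tps[:-1], tps[1:]):
        tab = (
            pd.crosstab(wide[t1], wide[t2])
            .reindex(index=cats, columns=cats, fill_value=0)
            .astype(int)
        )
        tab.index.name = "from"
        tab.columns.name = "to"
        tables[(t1, t2)] = tab
        for c in cats:
            seen[c] += int(tab.loc[c].sum())
            retained[c] += int(tab.loc[c, c])

    arr = wide.to_numpy(dtype=object)
    stability_rows = []
    for c in cats:
        ever = (arr == c).any(axis=1)
        always = (arr == c).all(axis=1)
        stability_rows.append(
            {
                "category": c,
                "adjacent_retention": retained[c] / seen[c] if seen[c] else np.nan,
                "full_series_stability": always.sum() / ever.sum() if ever.sum() else np.nan,
                "n_ever": int(ever.sum()),
            }
        )
    stability = pd.DataFrame(stability_rows).set_index("category")
    return tables, stability
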