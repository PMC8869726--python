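"""One-sided Fisher's-exact-test over-representation of annotation terms.

For a member set of size n drawn from a background of N genes, of which
K carry a term and k of the members do, the over-representation p is
the upper hypergeometric tail P(X >= k) — the one-sided (greater)
Fisher exact p of the 2x2 table [[k, n-k], [K-k, N-n-K+k]].  Thresholds
follow the analysis stage: 0.01 for TF families in clusters, 0.05 for
pathway terms in bias categories; raw p-values are used (no multiple-
testing correction) unless BH is requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _annotation_to_terms(annotation) -> dict:
    """gene->set-of-terms from a (gene_id, term_id) frame or mapping."""
    if isinstance(annotation, pd.DataFrame):
        return annotation.groupby("gene_id")["term_id"].agg(set).to_dict()
    return {g: set(t) for g, t in annotation.items()}


def fisher_enrichment(member_sets: dict, annotation, background,
                      alpha: float = 0.01, bh: bool = False) -> pd.DataFrame:
    """Test every (member set, term) pair for over-representation.

    Parameters
    ----------
    member_sets : mapping of set label -> gene set (subsets of the
        background).
    annotation : (gene_id, term_id) frame or gene->terms mapping;
        entries outside the background are ignored.
    background : the gene universe.
    alpha : significance threshold on the (raw or, with ``bh=True``,
        adjusted) p-value.

    Returns
    -------
    DataFrame with one row per (set, term): k, n, K, N, odds_ratio
    (Haldane 0.5 correction when any cell is zero), p, significant.
    """
    background = set(background)
    N = len(background)
    if N == 0:
        raise ValueError("empty background")
    for label, genes in member_sets.items():
        outside = set(genes) - background
        if outside:
            raise ValueError(
                f"member set {label!r} has genes outside the background: "
                f"{sorted(outside)[:3]}"
            )
    gene_terms = _annotation_to_terms(annotation)
    term_genes: dict[str, set] = {}
    for g, terms in gene_terms.items():
        if g in background:
            for t in terms:
                term_genes.setdefault(t, set()).add(g)

    rows = []
    for label, genes in member_sets.items():
        genes = set(genes)
        n = len(genes)
        for term in sorted(term_genes):
            K = len(term_genes[term])
            k = len(genes & term_genes[term])
            # upper tail P(X >= k), X ~ Hypergeom(N, K, n)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            p = min(p, 1.0)
            a, b = k, n - k
            c, d = K - k, N - n - K + k
            if min(a, b, c, d) == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            rows.append(
                {"set_label": label, "term_id": term, "k": k, "n": n,
                 "K": K, "N": N, "odds_ratio": (a * d) / (b * c), "p": p}
            )
    out = pd.DataFrame(rows, columns=["set_label", "term_id", "k", "n", "K", "N",
                                      "odds_ratio", "p"])
    if bh and len(out):
        from .diffexpr import bh_adjust

        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def enrichment_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Set x term table of -log10 p with insignificant cells masked (NaN)."""
    if not len(results):
        return pd.DataFrame()
    vals = results.copy()
    vals["neglog10p"] = -np.log10(vals["p"])
    vals.loc[~vals["significant"], "neglog10p"] = np.nan
    return vals.pivot(index="set_label", columns="term_id", values="neglog10p")
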