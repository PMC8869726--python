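"""Triad bias classification: centroids, Low gate, transitions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadyn import quantify, triad_bias
from triadyn.containers import ExpressionMatrix
from triadyn.triad_bias import (CATEGORIES, CENTROIDS, LOW, classify_all,
                                classify_fractions, classify_triad,
                                relative_contributions, ternary_coordinates,
                                transitions)
from triadyn.synthetic import SimulationConfig, simulate_dataset

from conftest import uniform_simplex


def brute_force_category(frac):
    """Independent nearest-centroid oracle with explicit tie-break order."""
    best, best_d = None, np.inf
    for cat in CATEGORIES:
        d = float(np.sqrt(((np.asarray(frac) - CENTROIDS[cat]) ** 2).sum()))
        if d < best_d - 1e-15:
            best, best_d = cat, d
    return best, best_d


class TestRelativeContributions:
    @pytest.mark.parametrize(
        "triple,expected",
        [((5, 5, 5), (1 / 3, 1 / 3, 1 / 3)),
         ((2, 0, 0), (1, 0, 0)),
         ((6, 2, 2), (0.6, 0.2, 0.2))],
    )
    def test_direct_ratios(self, triple, expected):
        np.testing.assert_allclose(relative_contributions(*triple), expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_contributions(0, 0, 0)


class TestClassifyTriad:
    @pytest.mark.parametrize("cat,centroid", list(CENTROIDS.items()))
    def test_exact_centroids(self, cat, centroid):
        got, dist = classify_triad(centroid)
        assert got == cat and dist == pytest.approx(0.0, abs=1e-12)

    def test_mild_bias_stays_balanced(self):
        # d(Balance) ~ 0.327 is the minimum over all seven centroids
        cat, dist = classify_triad((0.6, 0.2, 0.2))
        assert cat == "Balance"
        assert dist == pytest.approx(np.sqrt(0.2667**2 + 2 * 0.1333**2), abs=1e-3)

    def test_matches_brute_force_on_random_simplex(self, rng):
        pts = uniform_simplex(2000, rng)
        cats, dists = classify_fractions(pts)
        for p, c, d in zip(pts, cats, dists):
            oc, od = brute_force_category(p)
            assert c == oc
            assert d == pytest.approx(od, abs=1e-12)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            classify_triad((0.5, 0.4, 0.4))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.tuples(*[st.floats(1e-6, 1.0) for _ in range(3)]))
    def test_distance_is_true_minimum_over_centroids(self, raw):
        frac = np.asarray(raw) / sum(raw)
        cat, dist = classify_triad(frac)
        all_d = {c: np.sqrt(((frac - CENTROIDS[c]) ** 2).sum()) for c in CATEGORIES}
        assert dist == pytest.approx(min(all_d.values()), abs=1e-12)
        assert all_d[cat] == pytest.approx(dist, abs=1e-12)


class TestTernary:
    def test_vertices_and_centroid(self):
        np.testing.assert_allclose(ternary_coordinates((1, 0, 0)), (0, 0))
        np.testing.assert_allclose(ternary_coordinates((0, 0, 1)), (0.5, np.sqrt(3) / 2))
        np.testing.assert_allclose(
            ternary_coordinates((1 / 3, 1 / 3, 1 / 3)), (0.5, np.sqrt(3) / 6)
        )

    def test_invertible_on_simplex(self, rng):
        pts = uniform_simplex(50, rng)
        xy = ternary_coordinates(pts)
        fd = xy[:, 1] / (np.sqrt(3) / 2)
        fb = xy[:, 0] - fd / 2
        np.testing.assert_allclose(np.column_stack([1 - fb - fd, fb, fd]), pts, atol=1e-12)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            ternary_coordinates((0.7, 0.7, -0.4))


def _matrix_from_means(means_by_gene, timepoints=("0", "2")):
    """Expression matrix with 2 identical replicates at each time point."""
    cols, meta = {}, {}
    for tp in timepoints:
        for r in (1, 2):
            sid = f"DAP{tp}_R{r}"
            cols[sid] = {g: v[tp] for g, v in means_by_gene.items()}
            meta[sid] = {"timepoint": tp, "replicate": r}
    return ExpressionMatrix(
        values=pd.DataFrame(cols),
        samples=pd.DataFrame(meta).T,
        unit="fpkm",
    )


class TestClassifyAll:
    def test_low_gate_and_balance(self):
        em = _matrix_from_means(
            {
                "t1_A": {"0": 0.2, "2": 10.0},
                "t1_B": {"0": 0.3, "2": 10.0},
                "t1_D": {"0": 0.4, "2": 10.0},
            }
        )
        triads = pd.DataFrame(
            {"gene_A": ["t1_A"], "gene_B": ["t1_B"], "gene_D": ["t1_D"]},
            index=pd.Index(["t1"], name="triad_id"),
        )
        out = classify_all(em, triads)
        at0 = out[out.timepoint == "0"].iloc[0]
        at2 = out[out.timepoint == "2"].iloc[0]
        assert at0.category == LOW and at0.total_fpkm == pytest.approx(0.9)
        assert np.isnan(at0.fA)
        assert at2.category == "Balance"

    def test_missing_member_is_named(self, small_fpkm, small_dataset):
        triads = small_dataset.triads.copy()
        triads.loc[triads.index[0], "gene_B"] = "not_a_gene"
        with pytest.raises(KeyError, match=triads.index[0]):
            classify_all(small_fpkm, triads)

    def test_noisy_recovery_on_planted_truth(self, small_fpkm, small_dataset):
        out = classify_all(small_fpkm, small_dataset.triads)
        merged = out.merge(small_dataset.truth.category, on=["triad_id", "timepoint"],
                           suffixes=("", "_true"))
        nonlow = merged[merged.category_true != LOW]
        assert (nonlow.category == nonlow.category_true).mean() >= 0.95
        low = merged[merged.category_true == LOW]
        assert (low.category == LOW).mean() >= 0.95

    def test_category_proportions_sum_to_one(self, small_fpkm, small_dataset):
        out = classify_all(small_fpkm, small_dataset.triads)
        for include_low in (True, False):
            props = triad_bias.category_proportions(out, include_low=include_low)
            np.testing.assert_allclose(props.sum(axis=1), 1.0)


def test_subgenome_permutation_equivariance(small_fpkm, small_dataset):
    """Permuting A/B/D columns permutes dominant/suppressed labels alike."""
    triads = small_dataset.triads.iloc[:100]
    base = classify_all(small_fpkm, triads)
    subs = ("A", "B", "D")
    cols = {"A": "gene_A", "B": "gene_B", "D": "gene_D"}
    for perm in itertools.permutations(subs):
        permuted = pd.DataFrame(
            {cols[s]: triads[cols[p]].to_numpy() for s, p in zip(subs, perm)},
            index=triads.index,
        )
        got = classify_all(small_fpkm, permuted)
        relabel = dict(zip(perm, subs))
        for b, g in zip(base.category, got.category):
            if b == LOW or b == "Balance":
                assert g == b
            else:
                sub, kind = b.split(" ")
                assert g == f"{relabel[sub]} {kind}"


class TestTransitions:
    def _assign(self, labels_by_tp):
        rows = []
        for tp, labels in labels_by_tp.items():
            for i, lab in enumerate(labels):
                rows.append({"triad_id": f"t{i}", "timepoint": tp, "category": lab})
        return pd.DataFrame(rows)

    def test_all_balance_conservation(self):
        a = self._assign({"0": ["Balance"] * 5, "2": ["Balance"] * 5})
        tables, stability = transitions(a)
        tab = tables[("0", "2")]
        assert tab.loc["Balance", "Balance"] == 5
        assert tab.to_numpy().sum() == 5
        assert stability.loc["Balance", "adjacent_retention"] == 1.0

    def test_row_sums_match_source_counts(self, small_fpkm, small_dataset):
        out = classify_all(small_fpkm, small_dataset.triads)
        tables, _ = transitions(out)
        counts = out.groupby(["timepoint", "category"]).size()
        for (t1, _t2), tab in tables.items():
            for cat in tab.index:
                expect = counts.get((t1, cat), 0)
                assert tab.loc[cat].sum() == expect

    def test_planted_switches_recovered_at_zero_noise(self):
        cfg = SimulationConfig(n_triads=400, bias_concentration=np.inf,
                               nb_dispersion=0.0, de_fraction=0.0,
                               switch_fraction=0.10, seed=21)
        ds = simulate_dataset(cfg)
        f = quantify.fpkm(ds.counts, ds.lengths)
        out = classify_all(f, ds.triads)
        tables, _ = transitions(out)
        off_diag = sum(
            tab.to_numpy().sum() - np.trace(tab.to_numpy()) for tab in tables.values()
        )
        truth = ds.truth.category.pivot(index="triad_id", columns="timepoint",
                                        values="category")
        truth = truth[[c for c in out.timepoint.unique()]]
        planted_changes = int((truth.to_numpy()[:, :-1] != truth.to_numpy()[:, 1:]).sum())
        assert off_diag == planted_changes
        assert planted_changes > 0

    def test_inconsistent_triad_sets_rejected(self):
        a = self._assign({"0": ["Balance"] * 3, "2": ["Balance"] * 3})
        with pytest.raises(ValueError):
            transitions(a.iloc[:-1])
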