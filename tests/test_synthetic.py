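"""Synthetic data generator: fraction draws, counts, dataset contracts."""

import numpy as np
import pandas as pd
import pytest

from triadyn import quantify
from triadyn.triad_bias import CATEGORIES, LOW, classify_all, classify_fractions
from triadyn.synthetic import (SimulationConfig, simulate_category_fractions,
                               simulate_counts, simulate_dataset,
                               temporal_templates, write_dataset)


class TestCategoryFractions:
    def test_balance_at_infinite_concentration(self, rng):
        frac = simulate_category_fractions("Balance", np.inf, rng)
        np.testing.assert_allclose(frac, 1 / 3)

    def test_dominant_limit_is_near_vertex(self, rng):
        frac = simulate_category_fractions("A dominant", np.inf, rng)
        cat, _ = classify_fractions(frac[None, :])
        assert cat[0] == "A dominant"
        assert frac[0] > 0.99

    def test_moderate_concentration_recovers_centroid(self, rng):
        # Monte-Carlo frequency against the nearest-centroid oracle
        draws = simulate_category_fractions("D suppressed", 50.0, rng, size=10_000)
        cats, _ = classify_fractions(draws)
        assert (cats == "D suppressed").mean() >= 0.95

    def test_simplex_and_validation(self, rng):
        for cat in CATEGORIES:
            draws = simulate_category_fractions(cat, 10.0, rng, size=100)
            np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)
            assert (draws > 0).all()
        with pytest.raises(ValueError):
            simulate_category_fractions("Low", 10.0, rng)
        with pytest.raises(ValueError):
            simulate_category_fractions("Balance", 0.0, rng)


class TestSimulateCounts:
    def test_zero_mean_gives_zero(self, rng):
        assert simulate_counts(0.0, 1000, 10**7, 0.1, rng) == 0

    def test_mean_matches_fpkm_inversion(self, rng):
        # mu = 1 FPKM * 1000 bp * 1e7 / 1e9 = 10
        draws = simulate_counts(np.ones(10_000), 1000, 10**7, 0.0, rng)
        se = np.sqrt(10 / 10_000)
        assert abs(draws.mean() - 10) < 3 * se

    def test_variance_matches_nb_identity(self, rng):
        # var = mu + alpha mu^2 = 10 + 2*100 = 210
        draws = simulate_counts(np.ones(20_000), 1000, 10**7, 2.0, rng)
        assert draws.var() == pytest.approx(210, rel=0.15)

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            simulate_counts(-1.0, 1000, 10**7, 0.1, rng)
        with pytest.raises(ValueError):
            simulate_counts(1e30, 1000, 10**12, 0.1, rng)


class TestTemplates:
    def test_flat_when_single_cluster(self):
        np.testing.assert_allclose(temporal_templates(6, 1), 0.0)

    def test_distinct_shapes(self):
        t = temporal_templates(6, 8)
        assert t.shape == (8, 6)
        # no two templates are perfectly correlated
        z = (t - t.mean(axis=1, keepdims=True)) / t.std(axis=1, keepdims=True)
        corr = z @ z.T / 6
        off = corr[~np.eye(8, dtype=bool)]
        assert (off < 0.999).all()


class TestSimulateDataset:
    def test_planted_truth_at_zero_noise(self):
        mix = {c: 0.0 for c in CATEGORIES}
        mix["Balance"] = 1.0
        mix[LOW] = 0.0
        cfg = SimulationConfig(n_triads=100, category_mix=mix,
                               bias_concentration=np.inf, nb_dispersion=0.0,
                               switch_fraction=0.0, de_fraction=0.0, seed=4)
        ds = simulate_dataset(cfg)
        fpkm = quantify.fpkm(ds.counts, ds.lengths)
        out = classify_all(fpkm, ds.triads)
        expressed = out[out.category != LOW]
        assert (expressed.category == "Balance").all()
        assert len(expressed) == len(out)

    def test_empty_dataset(self):
        ds = simulate_dataset(SimulationConfig(n_triads=0, seed=1))
        assert ds.counts.values.shape[0] == 0
        assert len(ds.triads) == 0

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_dataset(SimulationConfig(n_triads=50, seed=7))
        b = simulate_dataset(SimulationConfig(n_triads=50, seed=7))
        c = simulate_dataset(SimulationConfig(n_triads=50, seed=8))
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.truth.category, b.truth.category)
        assert not a.counts.values.equals(c.counts.values)

    def test_truth_consistency(self, small_dataset):
        # planted Low cells sit below the expressed threshold and
        # expressed cells above it, by construction of the guard band
        truth = small_dataset.truth
        totals = truth.planted_fpkm.copy()
        triad_of = pd.Series([g.rsplit("_", 1)[0] for g in totals.index],
                             index=totals.index)
        triad_totals = totals.groupby(triad_of).sum()
        cat = truth.category.pivot(index="triad_id", columns="timepoint",
                                   values="category")[totals.columns]
        low_mask = cat.to_numpy() == LOW
        assert (triad_totals.to_numpy()[low_mask] <= 1.0).all()
        assert (triad_totals.to_numpy()[~low_mask] > 1.0).all()

    def test_planted_de_has_expected_log2fc(self):
        cfg = SimulationConfig(n_triads=200, n_clusters_planted=1, de_fraction=0.15,
                               de_log2fc=2.0, bias_concentration=np.inf,
                               switch_fraction=0.0, seed=13)
        ds = simulate_dataset(cfg)
        fp = ds.truth.planted_fpkm
        assert len(ds.truth.de) > 0
        for _, row in ds.truth.de.iterrows():
            t1, t2 = row.contrast.split("->")
            observed = np.log2(fp.loc[row.gene_id, t2] / fp.loc[row.gene_id, t1])
            assert observed == pytest.approx(row.sign * 2.0, abs=1e-9)

    def test_fpkm_scale_realism(self):
        # realized FPKM converges to planted FPKM at low noise / deep libraries
        cfg = SimulationConfig(n_triads=300, nb_dispersion=0.0,
                               n_clusters_planted=1, de_fraction=0.0,
                               library_size_range=(200_000_000, 200_000_001),
                               seed=3)
        ds = simulate_dataset(cfg)
        fpkm = quantify.fpkm(ds.counts, ds.lengths)
        realized = fpkm.timepoint_means().to_numpy()
        planted = ds.truth.planted_fpkm.to_numpy()
        mask = planted > 1
        rel = np.abs(realized[mask] - planted[mask]) / planted[mask]
        assert np.median(rel) < 0.05

    def test_category_mix_must_sum_to_one(self):
        mix = {c: 0.2 for c in CATEGORIES}
        with pytest.raises(ValueError):
            SimulationConfig(n_triads=10, category_mix=mix)

    def test_written_files_roundtrip(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, tmp_path)
        assert all(p.exists() for p in paths)
        counts = pd.read_csv(tmp_path / "counts.tsv", sep="\t", index_col=0)
        pd.testing.assert_frame_equal(counts, small_dataset.counts.values,
                                      check_dtype=False)
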