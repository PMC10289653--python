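"""Scaled-TPM aggregation, bootstrap intervals and pseudobulk oracles."""

import numpy as np
import pandas as pd
import pytest

import atlasinfer as ai


def brute_scaled_tpm(counts, labels):
    """Independent step-by-step oracle: size factors, per-type gene
    means, renormalisation to one million."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    geo = np.exp(np.mean(np.log(totals)))
    norm = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        norm[:, j] = counts[:, j] / (totals[j] / geo)
    out = {}
    for ct in sorted(set(labels)):
        cols = [j for j, l in enumerate(labels) if l == ct]
        means = np.array([np.mean([norm[g, j] for j in cols]) for g in range(counts.shape[0])])
        out[ct] = means / means.sum() * 1e6
    return out


class TestSizeFactor:
    def test_equal_totals_unchanged(self):
        counts = np.tile([[2], [3]], (1, 4))
        out = ai.size_factor_normalize(counts)
        np.testing.assert_allclose(out, counts)

    def test_two_cell_closed_form(self):
        counts = np.array([[10.0, 1000.0]])
        out = ai.size_factor_normalize(counts)
        # geometric mean of totals = 100 -> size factors (0.1, 10)
        np.testing.assert_allclose(out, [[100.0, 100.0]])

    def test_random_matrix_matches_oracle(self, rng):
        counts = rng.integers(1, 20, size=(5, 6)).astype(float)
        totals = counts.sum(axis=0)
        geo = np.exp(np.mean(np.log(totals)))
        expected = counts / (totals / geo)
        np.testing.assert_allclose(ai.size_factor_normalize(counts), expected)

    def test_geometric_mean_preserved(self, rng):
        counts = rng.integers(1, 30, size=(8, 10)).astype(float)
        out = ai.size_factor_normalize(counts)
        geo_in = np.exp(np.mean(np.log(counts.sum(axis=0))))
        geo_out = np.exp(np.mean(np.log(out.sum(axis=0))))
        assert geo_out == pytest.approx(geo_in)

    def test_zero_total_cell_named(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="cellB"):
            ai.size_factor_normalize(counts, cell_names=["cellA", "cellB"])


class TestScaledTPM:
    def test_single_nonzero_gene_gets_million(self):
        counts = np.array([[5.0, 3.0], [0.0, 0.0]])
        prof = ai.aggregate_scaled_tpm(counts, np.array(["t", "t"]))
        np.testing.assert_allclose(prof.scaled_tpm["t"], [1e6, 0.0])

    def test_columns_sum_to_million(self, default_atlas):
        ds, labels = default_atlas
        norm = ai.size_factor_normalize(ds.counts, ds.cells)
        prof = ai.aggregate_scaled_tpm(norm, labels, genes=ds.genes)
        np.testing.assert_allclose(prof.scaled_tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_toy_matrix_matches_hand_oracle(self, rng):
        counts = rng.integers(0, 9, size=(3, 4)) + np.eye(3, 4, dtype=int)
        counts[:, 0] += 1  # keep totals positive
        labels = np.array(["a", "a", "b", "b"])
        norm = ai.size_factor_normalize(counts)
        prof = ai.aggregate_scaled_tpm(norm, labels)
        expected = brute_scaled_tpm(counts, labels)
        for ct in ("a", "b"):
            np.testing.assert_allclose(prof.scaled_tpm[ct], expected[ct], rtol=1e-12)

    def test_permuting_cells_leaves_profile_unchanged(self, rng):
        counts = rng.integers(0, 10, size=(6, 12)) + 1
        labels = np.array(list("aabbcc") * 2)
        perm = rng.permutation(12)
        p1 = ai.aggregate_scaled_tpm(ai.size_factor_normalize(counts), labels)
        p2 = ai.aggregate_scaled_tpm(
            ai.size_factor_normalize(counts[:, perm]), labels[perm]
        )
        np.testing.assert_allclose(p1.scaled_tpm, p2.scaled_tpm)

    def test_unknown_label_subsets_rejected(self):
        with pytest.raises(ValueError):
            ai.aggregate_scaled_tpm(np.ones((2, 3)), np.array(["a", "b"]))


class TestBootstrap:
    def test_allzero_gene_not_robust(self):
        counts = np.vstack([np.zeros(20), np.ones(20)])
        prof = ai.bootstrap_profile(counts, np.array(["t"] * 20), n_boot=100, seed=0)
        assert prof.ci_low[95].iloc[0, 0] == 0 == prof.ci_high[95].iloc[0, 0]
        assert not prof.robust_mask.iloc[0, 0]

    def test_always_expressed_gene_robust(self, rng):
        counts = rng.integers(1, 5, size=(3, 30))
        prof = ai.bootstrap_profile(counts, np.array(["t"] * 30), n_boot=100, seed=0)
        assert prof.robust_mask.all().all()
        assert (prof.ci_low[95] > 0).all().all()

    def test_seeded_bootstrap_reproducible(self, rng):
        counts = rng.integers(0, 6, size=(10, 40)) + 1
        labels = np.array(["a", "b"] * 20)
        p1 = ai.bootstrap_profile(counts, labels, n_boot=150, seed=7)
        p2 = ai.bootstrap_profile(counts, labels, n_boot=150, seed=7)
        for lvl in (95, 80):
            pd.testing.assert_frame_equal(p1.ci_low[lvl], p2.ci_low[lvl])
            pd.testing.assert_frame_equal(p1.ci_high[lvl], p2.ci_high[lvl])

    def test_ci_orders_and_nesting(self, rng):
        counts = rng.poisson(2.0, size=(30, 50))
        prof = ai.bootstrap_profile(counts, np.array(["t"] * 50), n_boot=300, seed=1)
        assert (prof.ci_low[95] <= prof.ci_low[80]).all().all()
        assert (prof.ci_high[80] <= prof.ci_high[95]).all().all()
        assert (prof.ci_low[95] <= prof.ci_high[95]).all().all()

    def test_robust_mask_within_detected(self, default_atlas, default_profile):
        ds, labels = default_atlas
        pct = ai.percent_expressed(ds.counts, labels, genes=ds.genes)
        mask = default_profile.robust_mask.to_numpy()
        assert (pct.pct.to_numpy()[mask] > 0).all()

    def test_interval_stability_in_n_boot(self, rng):
        """Going from 1000 to 5000 replicates moves CI endpoints by
        < 5% relative for well-expressed genes of one synthetic type."""
        counts = rng.poisson(rng.gamma(10, 0.2, size=(100, 1))[:, 0][:, None] * np.ones((100, 150)))
        labels = np.array(["t"] * 150)
        a = ai.bootstrap_profile(counts, labels, n_boot=1000, seed=2)
        b = ai.bootstrap_profile(counts, labels, n_boot=5000, seed=2)
        well = a.scaled_tpm["t"] > 5000
        for side, lvl in ((a.ci_low, 95), (a.ci_high, 95)):
            x = side[lvl].loc[well, "t"].to_numpy()
            y = (b.ci_low if side is a.ci_low else b.ci_high)[lvl].loc[well, "t"].to_numpy()
            assert np.all(np.abs(x - y) / np.maximum(y, 1) < 0.05)

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            ai.bootstrap_profile(np.ones((2, 3)), np.array(["t"] * 3), n_boot=1)


class TestPercentExpressed:
    def test_closed_forms(self):
        counts = np.array([[1, 2, 3, 4], [0, 0, 0, 1]])
        pct = ai.percent_expressed(counts, np.array(["t"] * 4))
        assert pct.pct.iloc[0, 0] == 100.0
        assert pct.pct.iloc[1, 0] == 25.0

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 3, size=(7, 9))
        labels = rng.choice(["a", "b"], size=9)
        pct = ai.percent_expressed(counts, labels)
        for g in range(7):
            for ct in ("a", "b"):
                cols = [j for j in range(9) if labels[j] == ct]
                expected = 100 * sum(counts[g, j] > 0 for j in cols) / len(cols)
                assert pct.pct.loc[g, ct] == pytest.approx(expected)


class TestLog1pCPM:
    def test_all_zero_gene_zero_everywhere(self):
        counts = np.array([[0, 0], [4, 5]])
        out = ai.aggregate_log1p_cpm(counts, np.array(["a", "b"]))
        assert (out.loc[0] == 0).all()

    def test_single_cell_closed_form(self):
        counts = np.array([[7], [0]])
        out = ai.aggregate_log1p_cpm(counts, np.array(["t"]))
        assert out.iloc[0, 0] == pytest.approx(np.log1p(1e6))

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 12, size=(6, 8)) + 1
        labels = rng.choice(["a", "b", "c"], size=8)
        out = ai.aggregate_log1p_cpm(counts, labels)
        for ct in set(labels):
            cols = [j for j in range(8) if labels[j] == ct]
            expected = np.mean(
                [np.log1p(counts[:, j] / counts[:, j].sum() * 1e6) for j in cols], axis=0
            )
            np.testing.assert_allclose(out[ct], expected, rtol=1e-12)
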