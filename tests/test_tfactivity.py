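"""Peak clustering, target assignment, regression and dendrograms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import atlasinfer as ai
from atlasinfer.aggregate import CellTypeProfile
from atlasinfer import tfactivity as tfa


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "apex", "tf", "stage", "signal"])


def tss_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestClustering:
    def test_gap_rule(self):
        p = peaks_df([("c", 100, "A", "s", 1), ("c", 250, "B", "s", 1), ("c", 460, "A", "s", 1)])
        clusters = tfa.cluster_peaks(p, gap=200)
        apexes = [sorted(p.loc[c.peak_index, "apex"]) for c in clusters]
        assert apexes == [[100, 250], [460]]  # gap 150 merges, 210 splits

    def test_exact_gap_starts_new_cluster(self):
        p = peaks_df([("c", 100, "A", "s", 1), ("c", 300, "B", "s", 1)])
        assert len(tfa.cluster_peaks(p, gap=200)) == 2

    def test_single_peak_single_cluster(self):
        clusters = tfa.cluster_peaks(peaks_df([("c", 5, "A", "s", 1)]))
        assert len(clusters) == 1 and len(clusters[0].peak_index) == 1

    def test_negative_apex_rejected(self):
        with pytest.raises(ValueError):
            tfa.cluster_peaks(peaks_df([("c", -1, "A", "s", 1)]))

    def test_partition_matches_gap_graph_oracle(self, rng):
        rows = [
            (f"chr{rng.integers(3)}", int(rng.integers(0, 30000)), "A", "s", 1.0)
            for _ in range(500)
        ]
        p = peaks_df(rows)
        clusters = tfa.cluster_peaks(p, gap=200)
        # every peak in exactly one cluster
        all_members = np.concatenate([c.peak_index for c in clusters])
        assert sorted(all_members) == list(range(len(p)))
        # brute-force connected components of the |gap|<200 same-chrom graph
        parent = list(range(len(p)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(p)), 2):
            if p.chrom[i] == p.chrom[j] and abs(int(p.apex[i]) - int(p.apex[j])) < 200:
                parent[find(i)] = find(j)
        oracle = {}
        for i in range(len(p)):
            oracle.setdefault(find(i), set()).add(i)
        ours = {frozenset(map(int, c.peak_index)) for c in clusters}
        assert ours == {frozenset(v) for v in oracle.values()}


class TestFiltering:
    @pytest.mark.parametrize("n_tfs,kept", [(1, False), (2, True), (70, True), (71, False)])
    def test_tf_count_boundaries(self, n_tfs, kept):
        rows = [("c", 10 * i, f"tf{i}", "s", 1.0) for i in range(n_tfs)]
        clusters = tfa.cluster_peaks(peaks_df(rows), gap=200)
        assert len(clusters) == 1
        assert bool(tfa.filter_clusters(clusters)) is kept

    def test_truth_decoys_removed(self, default_atlas):
        ds, _ = default_atlas
        clusters = tfa.cluster_peaks(ds.peaks)
        kept = tfa.filter_clusters(clusters)
        for chrom, start, end in ds.truth.decoy_hot_regions:
            assert not any(
                c.chrom == chrom and start <= c.mean_apex <= end and len(c.tf_set) > 70
                for c in kept
            )
        singleton_keys = {
            (c.chrom, int(p.apex), p.tf)
            for c in kept
            for _, p in ds.peaks.loc[c.peak_index].iterrows()
        }
        for key in ds.truth.singleton_peaks:
            chrom, apex, tf = key.split(":")
            if (chrom, int(apex), tf) in singleton_keys:
                # a singleton may survive only by merging into a >=2-TF cluster
                c = next(
                    c for c in kept
                    if c.chrom == chrom
                    and any(int(p.apex) == int(apex) and p.tf == tf
                            for _, p in ds.peaks.loc[c.peak_index].iterrows())
                )
                assert len(c.tf_set) >= 2


class TestAssignment:
    def cluster_at(self, pos, chrom="c"):
        p = peaks_df([(chrom, pos, "A", "s", 1.0), (chrom, pos, "B", "s", 1.0)])
        return tfa.cluster_peaks(p)

    @pytest.mark.parametrize(
        "apex,tss1,tss2,expected",
        [
            (1000, 2000, 6000, "g1"),   # d1=1000, d2=5000 -> assigned
            (500, 2000, 2500, None),    # d1=1500, d2=2000 < 1.5*1500 -> no
            (4500, 2000, 9000, None),   # wait recomputed below
        ],
    )
    def test_rules(self, apex, tss1, tss2, expected):
        if apex == 4500:  # d1 = 2500 > 2000: distance rule fails
            tss1, tss2 = 7000, 13500
        clusters = self.cluster_at(apex)
        tss = tss_df([("g1", "c", tss1, "+"), ("g2", "c", tss2, "+")])
        out = tfa.assign_targets(clusters, tss)
        assert out[0].target_gene == expected

    def test_exact_tss_hit_assigned(self):
        clusters = self.cluster_at(5000)
        tss = tss_df([("g1", "c", 5000, "+"), ("g2", "c", 5001, "+")])
        assert tfa.assign_targets(clusters, tss)[0].target_gene == "g1"

    def test_equidistant_tie_unassigned(self):
        clusters = self.cluster_at(5000)
        tss = tss_df([("g1", "c", 4000, "+"), ("g2", "c", 6000, "+")])
        assert tfa.assign_targets(clusters, tss)[0].target_gene is None

    def test_chrom_without_tss_is_skipped(self):
        clusters = self.cluster_at(100, chrom="other")
        tss = tss_df([("g1", "c", 100, "+")])
        assert tfa.assign_targets(clusters, tss)[0].target_gene is None

    def test_translation_invariance(self, default_atlas):
        ds, _ = default_atlas
        peaks = ds.peaks.copy()
        shift = 12345
        clusters = tfa.assign_targets(
            tfa.filter_clusters(tfa.cluster_peaks(peaks)), ds.gene_annotation
        )
        peaks2 = peaks.assign(apex=peaks.apex + shift)
        tss2 = ds.gene_annotation.assign(tss=ds.gene_annotation.tss + shift)
        clusters2 = tfa.assign_targets(
            tfa.filter_clusters(tfa.cluster_peaks(peaks2)), tss2
        )
        assert [c.target_gene for c in clusters] == [c.target_gene for c in clusters2]


class TestNormalization:
    def test_rank_closed_forms(self):
        p = peaks_df([("c", 1, "A", "s", 3.0), ("c", 2, "A", "s", 7.0), ("c", 3, "A", "s", 9.0)])
        out = tfa.normalize_signals(p)
        np.testing.assert_allclose(out.norm_signal, [1 / 3, 2 / 3, 1.0])

    def test_tied_strengths_average_rank(self):
        p = peaks_df([("c", 1, "A", "s", 5.0), ("c", 2, "A", "s", 5.0)])
        out = tfa.normalize_signals(p)
        np.testing.assert_allclose(out.norm_signal, [0.75, 0.75])

    def test_matches_sort_oracle(self, rng):
        sig = rng.uniform(1, 100, size=200)
        p = peaks_df([("c", i, "A", "s", s) for i, s in enumerate(sig)])
        out = tfa.normalize_signals(p)
        order = np.argsort(np.argsort(sig)) + 1
        np.testing.assert_allclose(out.norm_signal, order / 200)

    def test_grouped_by_experiment(self):
        p = peaks_df([("c", 1, "A", "s1", 9.0), ("c", 2, "A", "s2", 1.0)])
        out = tfa.normalize_signals(p)
        np.testing.assert_allclose(out.norm_signal, [1.0, 1.0])

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            tfa.normalize_signals(peaks_df([("c", 1, "A", "s", 0.0)]))


class TestPredictorMatrix:
    def test_max_rule(self):
        p = tfa.normalize_signals(
            peaks_df([
                ("c", 100, "A", "s", 4.0), ("c", 150, "B", "s", 2.0),
                ("c", 5000, "A", "s", 9.0), ("c", 5050, "B", "s", 1.0),
            ])
        )
        clusters = tfa.cluster_peaks(p)
        for c in clusters:
            c.target_gene = "g"
        X = tfa.build_predictor_matrix(clusters, p)
        # A's norm signals are 0.5 and 1.0 -> max 1.0
        assert X.loc["g", "A"] == 1.0

    def test_duplicated_peak_idempotent(self):
        # duplicate after normalisation: max aggregation is idempotent
        rows = [("c", 100, "A", "s", 4.0), ("c", 120, "B", "s", 2.0)]
        p1 = tfa.normalize_signals(peaks_df(rows))
        p2 = pd.concat([p1, p1.iloc[[0]]], ignore_index=True)
        c1 = tfa.cluster_peaks(p1)
        c2 = tfa.cluster_peaks(p2)
        for c in c1 + c2:
            c.target_gene = "g"
        X1 = tfa.build_predictor_matrix(c1, p1)
        X2 = tfa.build_predictor_matrix(c2, p2)
        pd.testing.assert_frame_equal(X1, X2)

    def test_matches_triple_loop_oracle(self, default_atlas):
        ds, _ = default_atlas
        peaks = tfa.normalize_signals(ds.peaks)
        kept = tfa.assign_targets(
            tfa.filter_clusters(tfa.cluster_peaks(peaks)), ds.gene_annotation
        )
        X = tfa.build_predictor_matrix(kept, peaks)
        expected = {}
        for c in kept:
            if c.target_gene is None:
                continue
            for i in c.peak_index:
                key = (c.target_gene, peaks.tf[i])
                expected[key] = max(expected.get(key, 0.0), peaks.norm_signal[i])
        for (g, t), v in expected.items():
            assert X.loc[g, t] == pytest.approx(v)
        assert np.count_nonzero(X.to_numpy()) == len(expected)


class TestRegression:
    @staticmethod
    def profile_from(y, genes):
        df = pd.DataFrame({"ct": y}, index=genes)
        return CellTypeProfile(scaled_tpm=df)

    def test_constant_response_all_zero(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, size=(60, 5)), index=[f"g{i}" for i in range(60)])
        prof = self.profile_from(np.full(60, 7.0), list(X.index))
        act = ai.fit_tf_models(X, prof, folds=10, seed=0, response="raw")
        assert (act.beta.to_numpy() == 0).all()

    def test_planted_signal_recovered(self, rng):
        n, p = 120, 31
        X = pd.DataFrame(
            rng.uniform(0, 1, size=(n, p)),
            index=[f"g{i}" for i in range(n)],
            columns=["A"] + [f"noise{j}" for j in range(p - 1)],
        )
        y = 2.0 * X["A"].to_numpy() + rng.normal(0, 0.05, n)
        act = ai.fit_tf_models(X, self.profile_from(y, list(X.index)),
                               folds=10, seed=0, response="raw")
        beta = act.beta["ct"]
        assert beta["A"] > 0
        assert beta.idxmax() == "A"
        assert act.cv_mse["ct"] <= np.var(y)

    def test_fewer_genes_than_folds_rejected(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, size=(5, 2)), index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            ai.fit_tf_models(X, self.profile_from(np.ones(5), list(X.index)), folds=10)


class TestDendrograms:
    def test_identical_columns_merge_first(self):
        m = pd.DataFrame({"a": [1.0, 2], "b": [1.0, 2], "c": [9.0, 9]})
        d = ai.build_dendrogram(m)
        first = d.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_separated_groups_merge_within_first(self, rng):
        cols = {}
        for gi, center in enumerate([0.0, 100.0, 200.0, 300.0]):
            for r in range(2):
                cols[f"g{gi}_{r}"] = center + rng.normal(0, 0.1, size=10)
        d = ai.build_dendrogram(pd.DataFrame(cols))
        leaves = list(cols)
        for a, b, _, _ in d.linkage[:4]:
            if a < 8 and b < 8:
                assert leaves[int(a)].split("_")[0] == leaves[int(b)].split("_")[0]

    def test_column_permutation_equivalent_tree(self, rng):
        m = pd.DataFrame(rng.normal(size=(12, 6)), columns=list("abcdef"))
        d1 = ai.build_dendrogram(m)
        d2 = ai.build_dendrogram(m[list("fedcba")])
        coph1 = dict(zip(itertools.combinations(d1.leaves, 2), hierarchy.cophenet(d1.linkage)))
        coph2 = dict(zip(itertools.combinations(d2.leaves, 2), hierarchy.cophenet(d2.linkage)))
        for pair, v in coph1.items():
            key = pair if pair in coph2 else (pair[1], pair[0])
            assert coph2[key] == pytest.approx(v)

    def test_nan_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2], "c": [2.0, 2]})
        with pytest.raises(ValueError):
            ai.build_dendrogram(m)


class TestBakersGamma:
    def test_self_correlation_is_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 6)), columns=list("abcdef"))
        d = ai.build_dendrogram(m)
        assert ai.bakers_gamma(d, d) == pytest.approx(1.0)

    def test_mismatched_leaves_rejected(self, rng):
        d1 = ai.build_dendrogram(pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd")))
        d2 = ai.build_dendrogram(pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abce")))
        with pytest.raises(ValueError):
            ai.bakers_gamma(d1, d2)

    def test_matches_cut_tree_oracle(self, rng):
        from scipy.stats import spearmanr

        for _ in range(5):
            m1 = pd.DataFrame(rng.normal(size=(8, 6)), columns=list("abcdef"))
            m2 = pd.DataFrame(rng.normal(size=(8, 6)), columns=list("abcdef"))
            d1, d2 = ai.build_dendrogram(m1), ai.build_dendrogram(m2)

            def depths(d):
                n = len(d.leaves)
                cuts = hierarchy.cut_tree(d.linkage)
                out = {}
                for i, j in itertools.combinations(range(n), 2):
                    k_max = max(
                        n - col for col in range(n) if cuts[i, col] == cuts[j, col]
                    )
                    out[tuple(sorted((d.leaves[i], d.leaves[j])))] = k_max
                return out

            da, db = depths(d1), depths(d2)
            keys = sorted(da)
            expected = spearmanr([da[k] for k in keys], [db[k] for k in keys]).statistic
            assert ai.bakers_gamma(d1, d2) == pytest.approx(expected, abs=1e-12)
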