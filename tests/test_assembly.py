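from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis

from porecology import assembly, synth
from porecology.assembly import (
    CommunitySeries,
    assign_process,
    beta_nri,
    bin_taxa,
    cophenetic_matrix,
    rc_metric,
    score_pairs,
    succession_trend,
)


class TestBinning:
    def test_two_clades_split(self, two_clade_tree):
        taxa = list("abcdef")
        dist = cophenetic_matrix(two_clade_tree, taxa)
        # brute-force check of the constructed distances
        for i, j in combinations(range(6), 2):
            same_clade = (taxa[i] in "abc") == (taxa[j] in "abc")
            assert dist[i, j] == pytest.approx(0.1 if same_clade else 0.5)
        bins = bin_taxa(two_clade_tree, taxa, d_max=0.2, min_bin_size=1)
        assert sorted(tuple(sorted(b.taxa)) for b in bins) == [
            ("a", "b", "c"), ("d", "e", "f")]

    def test_star_tree_singleton_bins(self, star_tree):
        bins = bin_taxa(star_tree, list("abcd"), d_max=0.2, min_bin_size=1)
        assert sorted(b.taxa for b in bins) == [("a",), ("b",), ("c",),
                                                ("d",)]

    def test_star_tree_forced_merge(self, star_tree):
        bins = bin_taxa(star_tree, list("abcd"), d_max=0.2, min_bin_size=4)
        assert len(bins) == 1
        assert sorted(bins[0].taxa) == list("abcd")

    def test_fewer_taxa_than_min_bin_warns(self, star_tree):
        with pytest.warns(UserWarning, match="single bin"):
            bins = bin_taxa(star_tree, list("abcd"), min_bin_size=12)
        assert len(bins) == 1

    def test_partition_property(self):
        regime = synth.AssemblyRegime(kind="neutral", n_taxa=30, seed=3)
        series, _ = synth.make_community_series(regime)
        bins = bin_taxa(series.tree, series.taxa, min_bin_size=5)
        seen = [t for b in bins for t in b.taxa]
        assert sorted(seen) == sorted(series.taxa)
        assert all(len(b) >= 5 for b in bins)


class TestBetaNRI:
    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for k in (3, 4, 5):
            d = rng.random((k, k))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            f = rng.integers(1, 20, size=k).astype(float)
            g = rng.integers(1, 20, size=k).astype(float)
            p, q = f / f.sum(), g / g.sum()
            obs = p @ d @ q
            null = [p @ d[np.ix_(pi, pi)] @ q
                    for pi in permutations(range(k))]
            expected = (obs - np.mean(null)) / np.std(null)
            got, flag = beta_nri(f, g, d, exhaustive=True)
            assert flag is None
            assert got == pytest.approx(expected, rel=1e-12)

    def test_clustered_communities_negative(self, two_clade_tree):
        taxa = list("abcdef")
        d = cophenetic_matrix(two_clade_tree, taxa)
        # all abundance inside the tight (a, b, c) clade in both samples
        f = np.array([10.0, 8.0, 12.0, 0.0, 0.0, 0.0])
        g = np.array([9.0, 11.0, 7.0, 0.0, 0.0, 0.0])
        score, _ = beta_nri(f, g, d, exhaustive=True)
        assert score < 0

    def test_insufficient_taxa_flagged(self):
        d = np.zeros((3, 3))
        score, flag = beta_nri(np.array([5.0, 0, 0]),
                               np.array([1.0, 2.0, 3.0]), d)
        assert np.isnan(score)
        assert flag == "insufficient-taxa"

    def test_zero_null_sd_flagged(self):
        d = np.ones((3, 3)) - np.eye(3)  # all distances equal
        score, flag = beta_nri(np.ones(3), np.ones(3), d, n_null=50, seed=0)
        assert np.isnan(score)
        assert flag == "zero-null-sd"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        f = rng.integers(1, 9, 8).astype(float)
        g = rng.integers(1, 9, 8).astype(float)
        a, _ = beta_nri(f, g, d, n_null=200, seed=42)
        b, _ = beta_nri(f, g, d, n_null=200, seed=42)
        assert a == b

    def test_standardization_calibration(self):
        # data generated by the taxa-shuffle null: scores mean ~0, sd ~1
        rng = np.random.default_rng(7)
        k = 10
        d = rng.random((k, k))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        scores = []
        for i in range(600):
            pi = rng.permutation(k)
            ds = d[np.ix_(pi, pi)]  # shuffle identities on the tree
            f = rng.integers(1, 30, k).astype(float)
            g = rng.integers(1, 30, k).astype(float)
            s, flag = beta_nri(f, g, ds, n_null=200,
                               seed=np.random.default_rng(i))
            if flag is None:
                scores.append(s)
        assert abs(np.mean(scores)) < 0.1
        assert 0.85 < np.std(scores) < 1.15


class TestRC:
    def test_boundaries_of_counting_definition(self):
        null = np.linspace(0.1, 0.5, 99)
        assert assembly._rc_score(0.9, null) == (1.0, None)  # above all
        assert assembly._rc_score(0.01, null) == (-1.0, None)  # below all
        # observed at the exact null median (odd n, symmetric ties)
        assert assembly._rc_score(0.3, null)[0] == 0.0

    def test_shuffle_null_extremes_on_data(self):
        # complete turnover scores high, identical alignment scores low
        f = np.array([100.0, 0.0, 0.0, 0.0])
        g = np.array([0.0, 100.0, 0.0, 0.0])
        rc, _ = rc_metric(f, g, null="shuffle", exhaustive=True)
        rc_same, _ = rc_metric(f, f.copy(), null="shuffle", exhaustive=True)
        assert rc_same < 0 < rc

    def test_range_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            k = rng.integers(3, 8)
            f = rng.integers(0, 50, k).astype(float)
            g = rng.integers(0, 50, k).astype(float)
            if f.sum() == 0 or g.sum() == 0:
                continue
            for null in ("pool", "shuffle"):
                rc, _ = rc_metric(f, g, n_null=100, seed=1, null=null)
                assert -1.0 <= rc <= 1.0

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for k in (3, 4, 5):
            f = rng.integers(1, 20, k).astype(float)
            g = rng.integers(1, 20, k).astype(float)
            obs = braycurtis(f, g)
            null = [braycurtis(f, np.array(pi))
                    for pi in permutations(g)]
            null = np.array(null)
            expected = 2 * ((null < obs - 1e-12).mean()
                            + 0.5 * (np.abs(null - obs) <= 1e-12).mean()) - 1
            got, _ = rc_metric(f, g, null="shuffle", exhaustive=True)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_median_of_null_is_zero(self):
        # symmetric construction: obs sits at the exact null median
        f = np.array([10.0, 10.0, 10.0])
        g = np.array([10.0, 10.0, 10.0])
        rc, flag = rc_metric(f, g, null="shuffle", exhaustive=True)
        assert rc == 0.0
        assert flag == "degenerate-null"

    def test_pool_null_calibrated_for_shared_pool(self):
        # two multinomial draws from one pool should not look exceptional
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(12))
        extremes = 0
        for i in range(40):
            f = rng.multinomial(300, p).astype(float)
            g = rng.multinomial(300, p).astype(float)
            rc, _ = rc_metric(f, g, n_null=200,
                              seed=np.random.default_rng(i), null="pool")
            extremes += abs(rc) > 0.95
        assert extremes <= 8

    def test_exhaustive_requires_shuffle(self):
        with pytest.raises(ValueError, match="shuffle"):
            rc_metric(np.ones(3), np.ones(3), null="pool", exhaustive=True)


class TestAssignProcess:
    def test_selection_thresholds(self):
        assert assign_process(-2.5, None)[0] == "HoS"
        assert assign_process(2.5, None)[0] == "HeS"

    def test_dispersal_and_drift(self):
        assert assign_process(0.5, 0.97)[0] == "DL"
        assert assign_process(0.5, -0.99)[0] == "HD"
        assert assign_process(0.0, 0.0)[0] == "DR"

    def test_boundary_inclusive_drift(self):
        assert assign_process(1.96, 0.95)[0] == "DR"
        assert assign_process(-1.96, -0.95)[0] == "DR"

    def test_undefined_bnri_falls_through_with_flag(self):
        label, flag = assign_process(np.nan, 0.99)
        assert label == "DL"
        assert flag == "undefined-bnri"

    def test_total_over_grid(self):
        for b in np.linspace(-3, 3, 13):
            for rc in np.linspace(-1, 1, 9):
                label, _ = assign_process(b, rc)
                assert label in assembly.PROCESSES


class TestAggregate:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=["process", "weight"])

    def test_single_process(self):
        df = self.frame([("HoS", 0.2)] * 5)
        fr = assembly.aggregate_processes(df)
        assert fr["HoS"] == 1.0

    def test_equal_split(self):
        df = self.frame([("HoS", 0.5), ("DR", 0.5)])
        fr = assembly.aggregate_processes(df)
        assert fr["HoS"] == pytest.approx(0.5)
        assert fr["DR"] == pytest.approx(0.5)

    def test_weighted(self):
        df = self.frame([("HoS", 0.9), ("DR", 0.1)])
        fr = assembly.aggregate_processes(df)
        assert fr["HoS"] == pytest.approx(0.9)
        assert fr["DR"] == pytest.approx(0.1)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        df = self.frame([(rng.choice(assembly.PROCESSES), rng.random())
                         for _ in range(50)])
        fr = assembly.aggregate_processes(df)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            assembly.aggregate_processes(self.frame([("HoS", 0.0)]))


class TestScorePairs:
    def test_reproducible_given_seed(self):
        regime = synth.AssemblyRegime(kind="neutral", n_taxa=25,
                                      n_samples=3, seed=1)
        series, _ = synth.make_community_series(regime)
        a = score_pairs(series, n_null=50, seed=9, min_bin_size=25)
        b = score_pairs(series, n_null=50, seed=9, min_bin_size=25)
        pd.testing.assert_frame_equal(a, b)

    def test_selection_regime_recovers_hos(self):
        regime = synth.AssemblyRegime(kind="homogeneous_selection",
                                      n_taxa=120, n_samples=4,
                                      selection_strength=4.0, n_reads=5000,
                                      seed=5)
        series, _ = synth.make_community_series(regime)
        scores = score_pairs(series, n_null=200, seed=3, min_bin_size=8)
        fr = assembly.aggregate_processes(scores)
        assert max(fr, key=fr.get) == "HoS"


class TestCommunityGenerator:
    def test_deterministic(self):
        regime = synth.AssemblyRegime(kind="neutral", n_taxa=20, seed=4)
        a, _ = synth.make_community_series(regime)
        b, _ = synth.make_community_series(regime)
        pd.testing.assert_frame_equal(a.abundance, b.abundance)

    def test_replicate_draws_more_similar_than_disjoint_pools(self):
        shared = synth.AssemblyRegime(kind="neutral", n_taxa=50,
                                      n_samples=2, seed=6)
        series_a, _ = synth.make_community_series(shared)
        disjoint = synth.AssemblyRegime(kind="dispersal_limitation",
                                        n_taxa=50, n_samples=2, seed=6)
        series_b, _ = synth.make_community_series(disjoint)

        def bc(series):
            m = series.abundance.to_numpy()
            return braycurtis(m[:, 0], m[:, 1])

        assert bc(series_a) < bc(series_b)
        assert bc(series_b) == 1.0  # disjoint pools: complete turnover

    def test_strong_selection_concentrates_on_one_clade(self):
        regime = synth.AssemblyRegime(kind="homogeneous_selection",
                                      n_taxa=40, n_samples=2,
                                      selection_strength=50.0, seed=2)
        series, _ = synth.make_community_series(regime)
        m = series.abundance.to_numpy()
        # dominant taxa of both samples coincide and are phylo-close
        top_a = set(np.argsort(m[:, 0])[-3:])
        top_b = set(np.argsort(m[:, 1])[-3:])
        assert top_a & top_b
        d = cophenetic_matrix(series.tree, series.taxa)
        members = sorted(top_a | top_b)
        within = d[np.ix_(members, members)]
        assert within[np.triu_indices(len(members), 1)].mean() < d[
            np.triu_indices(40, 1)].mean()

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            synth.AssemblyRegime(kind="neutral", selection_strength=1.0)
        with pytest.raises(ValueError):
            synth.AssemblyRegime(kind="homogeneous_selection")
        with pytest.raises(ValueError):
            synth.AssemblyRegime(kind="banana")


class TestSuccession:
    def test_identical_communities_flagged(self):
        ab = pd.DataFrame(np.ones((5, 4)))
        table, r, p, flag = succession_trend(ab, [0, 12, 24, 36])
        assert (table["bray_curtis"] == 0).all()
        assert np.isnan(r)
        assert flag == "constant-series"

    def test_geometric_convergence_negative_trend(self):
        target = np.array([5.0, 3.0, 2.0])
        start = np.array([9.0, 0.5, 0.5])
        cols = {}
        for k in range(6):
            cols[f"s{k}"] = target + 0.5**k * (start - target)
        ab = pd.DataFrame(cols)
        times = np.arange(6) * 12.0
        table, r, p, flag = succession_trend(ab, times)
        bc = table["bray_curtis"].to_numpy()
        assert (np.diff(bc) < 0).all()
        assert r < 0

    def test_complete_turnover(self):
        ab = pd.DataFrame({"s0": [1.0, 0.0], "s1": [0.0, 1.0],
                           "s2": [1.0, 0.0], "s3": [0.0, 1.0]})
        table, _, _, _ = succession_trend(ab, [0, 1, 2, 3])
        assert (table["bray_curtis"] == 1.0).all()

    def test_too_few_intervals(self):
        ab = pd.DataFrame({"s0": [1.0, 2.0], "s1": [2.0, 1.0],
                           "s2": [1.0, 2.0]})
        _, r, _, flag = succession_trend(ab, [0, 1, 2])
        assert flag in ("too-few-intervals", "constant-series") or not np.isnan(r)


class TestCommunitySeries:
    def test_taxa_must_map_to_tips(self, star_tree):
        ab = pd.DataFrame({"s0": [1, 2], "s1": [2, 1]},
                          index=["a", "zzz"])
        with pytest.raises(ValueError, match="tree tip"):
            CommunitySeries(abundance=ab, sample_time=[0, 12],
                            tree=star_tree)

    def test_negative_counts_rejected(self, star_tree):
        ab = pd.DataFrame({"s0": [1, -2], "s1": [2, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="nonnegative"):
            CommunitySeries(abundance=ab, sample_time=[0, 12],
                            tree=star_tree)
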