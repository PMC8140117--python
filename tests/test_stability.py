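import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import syncliptic as sc
from syncliptic.io import CountMatrix
from syncliptic import _nb


class TestCpmAndFilters:
    def test_cpm_basics(self):
        cm = CountMatrix(
            pd.DataFrame({"s1": [10, 0]}), lib_size=pd.Series({"s1": 1e6})
        )
        out = sc.cpm(cm)
        assert out.iloc[0, 0] == pytest.approx(10.0)
        assert out.iloc[1, 0] == 0.0

    def test_cpm_scale_invariance(self):
        df = pd.DataFrame({"a": [5, 10, 25]})
        c1 = sc.cpm(CountMatrix(df))
        c2 = sc.cpm(CountMatrix(2 * df))
        pd.testing.assert_frame_equal(c1, c2)

    def test_filters_match_hand_enumeration(self):
        # 6-sample toy matrix with hand-computed keeps per rule
        df = pd.DataFrame(
            [
                [0, 0, 0, 0, 0, 0],  # g0: all zero
                [3, 3, 3, 3, 1, 1],  # g1: total 14
                [50, 60, 45, 70, 0, 0],  # g2: high in 4 samples
                [12, 13, 14, 15, 16, 11],  # g3: >10 everywhere
                [11, 11, 11, 0, 0, 0],  # g4: >10 in half
                [2, 2, 2, 2, 2, 2],  # g5: low everywhere
            ],
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(6)],
        )
        cm = CountMatrix(df)
        lib = cm.lib_size
        # armor: cpm >= 10/median(lib)*1e6 in >=4 samples and total >= 15
        thresh = 10 / np.median(lib) * 1e6
        cpm = sc.cpm(cm)
        expected_armor = df.index[
            ((cpm >= thresh).sum(axis=1) >= 4) & (df.sum(axis=1) >= 15)
        ]
        assert list(sc.filter_expressed(cm, "armor")) == list(expected_armor)
        assert "g1" not in sc.filter_expressed(cm, "armor")  # total 14 < 15
        # count_fraction: > 10 in at least 2/3 of 6 samples (4 samples)
        kept = sc.filter_expressed(cm, "count_fraction")
        assert list(kept) == ["g2", "g3"]
        # cpm_all
        kept = sc.filter_expressed(cm, "cpm_all", threshold=1)
        cpm_ok = (cpm >= 1).all(axis=1)
        assert list(kept) == list(df.index[cpm_ok])
        # zero gene dropped by every rule
        for rule in ("armor", "count_fraction", "cpm_all"):
            assert "g0" not in sc.filter_expressed(cm, rule)

    def test_unknown_rule(self):
        cm = CountMatrix(pd.DataFrame({"a": [1]}))
        with pytest.raises(ValueError):
            sc.filter_expressed(cm, "nope")


class TestBhFdr:
    def test_direct_formula(self):
        q = sc.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert sc.bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)
        np.testing.assert_allclose(sc.bh_fdr(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.bh_fdr(np.array([0.5, 1.5]))


class TestNbDeTwoGroup:
    def test_identical_counts_are_null(self):
        df = pd.DataFrame(
            np.vstack([np.full(8, 50), [3, 9, 4, 8, 5, 7, 6, 6]]),
            index=["flat", "noisy"],
        )
        de = sc.nb_de_two_group(CountMatrix(df), ["a"] * 4 + ["b"] * 4)
        assert de.loc["flat", "logFC"] == pytest.approx(0.0, abs=1e-6)
        assert de.loc["flat", "p"] == pytest.approx(1.0, abs=1e-4)

    def test_null_simulation_calibrated(self):
        rng = np.random.default_rng(21)
        mu = rng.lognormal(np.log(100), 1.0, 5000)
        X = _nb.nb_rvs(rng, np.tile(mu[:, None], 12), 0.05)
        de = sc.nb_de_two_group(
            CountMatrix(pd.DataFrame(X)), ["a"] * 6 + ["b"] * 6
        )
        assert 0.03 <= (de["p"] < 0.05).mean() <= 0.08

    def test_recovery_of_fourfold_changes(self):
        rng = np.random.default_rng(22)
        n = 2000
        mu = rng.lognormal(np.log(100), 1.0, n)
        changed = np.zeros(n, dtype=bool)
        changed[rng.choice(n, n // 10, replace=False)] = True
        M = np.tile(mu[:, None], 12).astype(float)
        M[changed, 6:] *= 4.0
        X = _nb.nb_rvs(rng, M, 0.05)
        de = sc.nb_de_two_group(CountMatrix(pd.DataFrame(X)), ["a"] * 6 + ["b"] * 6)
        assert de.loc[changed, "q"].median() < 0.05
        assert (de.loc[changed, "logFC"] > 0).mean() >= 0.95

    def test_small_group_rejected(self):
        cm = CountMatrix(pd.DataFrame(np.ones((3, 3), dtype=int)))
        with pytest.raises(ValueError):
            sc.nb_de_two_group(cm, ["a", "b", "b"])


class TestCorrelationDistance:
    def test_closed_form_cases(self):
        profiles = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1], [1, -1, 1, -1], [1, 1, -1, -1]],
            index=list("abcde"),
        )
        D, degenerate = sc.correlation_distance(profiles)
        assert D[0, 1] == pytest.approx(0.0)  # R = 1
        assert D[0, 2] == pytest.approx(1.0)  # R = -1
        assert D[3, 4] == pytest.approx(0.5)  # R = 0
        assert not degenerate.any()

    def test_metric_properties_and_affine_invariance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        D, _ = sc.correlation_distance(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0 and D.max() <= 1
        D2, _ = sc.correlation_distance(X * 3.5 - 1.25)
        np.testing.assert_allclose(D, D2, atol=1e-12)

    def test_degenerate_profiles_get_uninformative_distance(self):
        profiles = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]])
        D, degenerate = sc.correlation_distance(profiles)
        assert degenerate.tolist() == [True, False]
        assert D[0, 1] == 0.5 and D[0, 0] == 0.0


class TestAverageLinkage:
    def test_merge_sequence_matches_scipy_oracle_on_12_points(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        merges = sc.average_linkage(D)
        Z = linkage(squareform(D, checks=False), method="average")
        np.testing.assert_allclose([m[2] for m in merges], Z[:, 2], rtol=1e-12)
        assert [m[3] for m in merges] == [int(s) for s in Z[:, 3]]
        labels = sc.average_linkage_cut(D, 3)
        ref = fcluster(Z, 3, criterion="maxclust")
        assert adjusted_rand_score(labels, ref) == 1.0

    def test_k_equals_n(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert sc.average_linkage_cut(D, 3).tolist() == [1, 2, 3]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            sc.average_linkage_cut(np.zeros((2, 2)), 5)

    def test_archetype_recovery(self):
        profiles, labels = sc.archetype_profiles(20, noise_sd=0.1, seed=3)
        D, _ = sc.correlation_distance(profiles)
        found = sc.average_linkage_cut(D, 3)
        assert adjusted_rand_score(labels, found) >= 0.9


class TestFisherOneSided:
    def test_enumeration_example(self):
        # N=10, K=4, n=5: P(X >= 4) = C(4,4)*C(6,1)/C(10,5) = 6/252
        assert sc.fisher_one_sided(4, 4, 5, 10) == pytest.approx(6 / 252, abs=1e-12)

    def test_zero_overlap_is_one(self):
        assert sc.fisher_one_sided(0, 4, 5, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_all_small_populations(self):
        from math import comb

        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        exact = sum(
                            comb(K, j) * comb(N - K, n - j)
                            for j in range(k, min(K, n) + 1)
                        ) / comb(N, n)
                        assert sc.fisher_one_sided(k, K, n, N) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError):
            sc.fisher_one_sided(6, 4, 5, 10)


class TestChiSquare:
    def test_uniform_table_is_null(self):
        res = sc.chi_square_association([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        res = sc.chi_square_association([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
        assert res.p == pytest.approx(0.00982, abs=1e-4)

    def test_low_expected_count_excluded(self):
        res = sc.chi_square_association([[1, 9], [2, 8]])
        assert res.excluded
        assert res.p is None
        assert res.expected.min() == pytest.approx(1.5)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            sc.chi_square_association([[0, 0], [5, 5]])


class TestBindingLocationClass:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            (["exon"] * 3 + ["three_prime_utr"], "exon"),
            (["exon", "exon", "three_prime_utr", "three_prime_utr"], "exon_plus_other"),
            (["exon", "intron", "intron", "intron"], "intron"),
            (["three_prime_utr", "three_prime_utr", "exon"], "three_prime_utr"),
            (["five_prime_utr", "five_prime_utr", "exon"], "exon_plus_other"),
            (["exon", "intron"], "exon_plus_other"),
        ],
    )
    def test_majority_rules(self, classes, expected):
        assert sc.binding_location_class(classes) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.binding_location_class([])


class TestFeatureLengths:
    def test_toy_transcript_partition(self, toy_annotation):
        lengths = sc.feature_lengths("gA", toy_annotation)
        assert lengths == {
            "transcript": 400,
            "cds": 200,
            "three_prime_utr": 100,
            "five_prime_utr": 100,
        }
        assert (
            lengths["five_prime_utr"] + lengths["cds"] + lengths["three_prime_utr"]
            == lengths["transcript"]
        )

    def test_noncoding_gene(self, toy_annotation):
        lengths = sc.feature_lengths("gC", toy_annotation)
        assert lengths["cds"] == 0 and lengths["three_prime_utr"] == 0
        assert lengths["transcript"] == 300

    def test_longest_transcript_chosen(self, toy_annotation):
        # gE.t1 has exonic length 400 vs t2's 200
        assert sc.feature_lengths("gE", toy_annotation)["transcript"] == 400

    def test_unknown_gene(self, toy_annotation):
        with pytest.raises(KeyError):
            sc.feature_lengths("nope", toy_annotation)


class TestLengthTests:
    def test_identical_groups_are_symmetric(self):
        a = np.array([1.0, 2, 3, 4, 5])
        rep = sc.length_tests(a, a.copy())
        assert rep.t_p == pytest.approx(0.5)

    def test_separated_groups_detected_one_sided(self):
        rng = np.random.default_rng(9)
        a = rng.normal(20, 1, 30)
        b = rng.normal(10, 1, 30)
        rep = sc.length_tests(a, b, alternative="greater")
        assert rep.t_p < 1e-10

    def test_tukey_calibrated_on_equal_means(self):
        rng = np.random.default_rng(10)
        ok = 0
        for _ in range(100):
            clusters = {str(k): rng.normal(5, 1, 25) for k in range(3)}
            rep = sc.length_tests(
                clusters["0"], clusters["1"], clusters=clusters
            )
            if (rep.tukey["p"] > 0.05).all():
                ok += 1
        assert ok >= 90

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sc.length_tests([1.0], [1.0, 2.0])


class TestPcaQc:
    def test_perfectly_correlated_genes_load_one_component(self):
        X = pd.DataFrame(
            [[1.0, 2, 3, 4], [2, 4, 6, 8]], index=["g1", "g2"], columns=list("abcd")
        )
        scores, frac = sc.pca_qc(X, top_n=None)
        assert frac[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 6)))
        _, frac = sc.pca_qc(X, top_n=None)
        assert frac.sum() == pytest.approx(1.0)

    def test_top_n_clamped(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 5)))
        s1, f1 = sc.pca_qc(X, top_n=1000)
        s2, f2 = sc.pca_qc(X, top_n=None)
        np.testing.assert_allclose(f1, f2)

    def test_constant_matrix_rejected(self):
        X = pd.DataFrame(np.ones((10, 4)))
        with pytest.raises(ValueError):
            sc.pca_qc(X)


class TestSignSplit:
    def test_directions_partition_significant_genes(self, stability_de):
        for de in stability_de.values():
            up, down = sc.split_by_direction(de, fdr=0.05)
            assert set(up).isdisjoint(down)
            sig = de[de["q"] < 0.05]
            assert set(up) | set(down) <= set(sig.index)
            assert (de.loc[up, "logFC"] > 0).all()
            assert (de.loc[down, "logFC"] < 0).all()
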