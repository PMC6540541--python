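import numpy as np
import pytest

import synkin
from synkin.errors import DataError, ParameterError
from synkin.synthetic import standardized_ground_truth


def brute_force_complete_linkage(dist):
    """Exhaustive agglomeration oracle: repeatedly merge the pair of
    clusters with the smallest maximum pairwise member distance."""
    clusters = {i: frozenset([i]) for i in range(dist.shape[0])}
    next_id = dist.shape[0]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a < b:
                    d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                    if best is None or d < best[0]:
                        best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
        heights.append(d)
        partitions.append(frozenset(clusters.values()))
    return np.array(heights), partitions


def partition_from_labels(labels):
    return frozenset(
        frozenset(np.flatnonzero(labels == lab)) for lab in np.unique(labels)
    )


class TestPairwiseAngle:
    def test_analytic_cases(self):
        e1, e2 = np.eye(17)[0], np.eye(17)[1]
        diag = (e1 + e2) / np.sqrt(2)
        V = np.stack([e1, e1, -e1, e2, diag])
        D = synkin.pairwise_angle(V)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)  # identical
        assert D[0, 2] == pytest.approx(0.0, abs=1e-12)  # sign-flipped
        assert D[0, 3] == pytest.approx(90.0, abs=1e-9)  # orthogonal
        assert D[0, 4] == pytest.approx(45.0, abs=1e-9)  # arccos(1/sqrt 2)

    def test_premetric_on_lines(self, rng):
        V = rng.standard_normal((40, 17))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        D = synkin.pairwise_angle(V)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0.0 and D.max() <= 90.0
        # sign invariance: d(v, w) == d(-v, w)
        D2 = synkin.pairwise_angle(np.vstack([-V[:1], V[1:]]))
        np.testing.assert_allclose(D, D2, atol=1e-9)

    def test_zero_vector_rejected_with_provenance(self):
        pool = synkin.PCPool(np.eye(17)[:3], [("a", 0), ("a", 1), ("b", 0)])
        pool.vectors[1] = 0.0
        with pytest.raises(DataError, match="'a'"):
            synkin.pairwise_angle(pool)


class TestCompleteLinkage:
    def test_three_point_merge_order_forced(self):
        D = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        Z = synkin.complete_linkage(D)
        np.testing.assert_allclose(Z[:, 2], [1.0, 10.0])
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_two_points_single_merge(self):
        D = np.array([[0.0, 3.5], [3.5, 0.0]])
        Z = synkin.complete_linkage(D)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(3.5)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ParameterError):
            synkin.complete_linkage(D)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            D = rng.uniform(1, 90, size=(n, n))
            D = np.triu(D, 1)
            D = D + D.T
            Z = synkin.complete_linkage(D)
            heights, partitions = brute_force_complete_linkage(D)
            np.testing.assert_allclose(Z[:, 2], heights, atol=1e-9)
            assert (np.diff(Z[:, 2]) >= -1e-12).all()
            # flat partition agreement at a cut between two merge heights
            if n > 2:
                cut = 0.5 * (heights[0] + heights[1])
                labels = synkin.cut_tree_at(Z, cut)
                assert partition_from_labels(labels) == partitions[0]


class TestSelectCut:
    def test_constructed_gap_two_clusters(self):
        Z = synkin.complete_linkage(_dist_with_heights([1.0, 2.0, 3.0, 50.0]))
        cut, labels = synkin.select_cut(Z)
        assert 3.0 < cut < 50.0
        assert len(np.unique(labels)) == 2

    def test_early_gap_three_clusters(self):
        Z = synkin.complete_linkage(_dist_with_heights([1.0, 10.0, 11.0]))
        cut, labels = synkin.select_cut(Z)
        assert 1.0 < cut < 10.0
        assert len(np.unique(labels)) == 3

    def test_no_gap_is_an_error(self):
        D = synkin.pairwise_angle(np.eye(17)[:4])  # all pairwise 90 deg
        Z = synkin.complete_linkage(D)
        with pytest.raises(DataError):
            synkin.select_cut(Z)


def _dist_with_heights(heights):
    """Chain construction whose complete-linkage merge heights are exactly
    the given increasing sequence (points merge one at a time)."""
    n = len(heights) + 1
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = heights[j - 1]
    return D


class TestVarianceAccounting:
    def test_count_fractions(self):
        labels = np.array([0] * 4 + [1] * 3 + [2] * 3)
        np.testing.assert_allclose(
            synkin.cluster_variance(labels), [0.4, 0.3, 0.3]
        )

    def test_single_cluster_fraction_one(self):
        assert synkin.cluster_variance(np.zeros(7, dtype=int))[0] == 1.0

    def test_fractions_sum_to_one_for_random_assignments(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 6, size=rng.integers(2, 60))
            fr = synkin.cluster_variance(labels)
            assert fr.sum() == pytest.approx(1.0, abs=1e-12)


class TestSelectSynergies:
    def test_prefix_reaching_threshold(self):
        sel = synkin.select_synergies(np.array([0.5, 0.3, 0.2]), 0.8)
        np.testing.assert_array_equal(sel, [0, 1])

    def test_single_dominant_cluster(self):
        sel = synkin.select_synergies(np.array([0.81, 0.1, 0.09]), 0.8)
        np.testing.assert_array_equal(sel, [0])

    def test_threshold_one_selects_all(self):
        sel = synkin.select_synergies(np.array([0.5, 0.25, 0.25]), 1.0)
        assert len(sel) == 3

    def test_unsorted_input_sorted_descending_with_stable_ties(self):
        sel = synkin.select_synergies(np.array([0.2, 0.4, 0.2, 0.2]), 0.8)
        np.testing.assert_array_equal(sel, [1, 0, 2])

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ParameterError):
            synkin.select_synergies(np.array([1.0]), 0.0)


class TestCharacterize:
    def test_sign_flipped_pair_collapses(self):
        v = np.eye(17)[0] * 0.6 + np.eye(17)[4] * 0.8
        mean, sd, n_subj = synkin.characterize_cluster(
            np.stack([v, -v]), ["a", "b"]
        )
        np.testing.assert_allclose(np.abs(mean), np.abs(v), atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)
        assert n_subj == 2

    def test_single_member(self):
        v = np.eye(17)[2]
        mean, sd, n_subj = synkin.characterize_cluster(v[None, :], ["a"])
        np.testing.assert_array_equal(mean, v)
        np.testing.assert_allclose(sd, 0.0)
        assert n_subj == 1

    def test_distinct_subject_count(self):
        V = np.tile(np.eye(17)[0], (3, 1))
        *_, n_subj = synkin.characterize_cluster(V, ["a", "a", "b"])
        assert n_subj == 2

    def test_noisy_copies_average_to_planted_direction(self, rng):
        planted = rng.standard_normal(17)
        planted /= np.linalg.norm(planted)
        members = planted + 0.05 * rng.standard_normal((3, 17))
        members /= np.linalg.norm(members, axis=1, keepdims=True)
        members[1] *= -1
        mean, *_ = synkin.characterize_cluster(members, list("abc"))
        cos = abs(mean @ planted) / np.linalg.norm(mean)
        assert cos > 0.99


class TestCatalog:
    def test_end_to_end_recovery_on_small_cohort(self, small_cohort):
        gt, _, manifest, sms, pcsets = small_cohort
        catalog = synkin.build_catalog(synkin.PCPool.from_pcsets(pcsets))
        gts = standardized_ground_truth(gt, np.stack([sm.scale for sm in sms]))
        K = gt.n_modules
        top = np.stack([c.mean_loading for c in catalog.clusters[:K]])
        cos = np.abs(top @ gts.T)
        assert sorted(cos.argmax(axis=1)) == list(range(K))  # one-to-one
        assert (cos.max(axis=1) > 0.95).all()

    def test_variance_fractions_sum_to_one(self, small_cohort):
        *_, pcsets = small_cohort
        catalog = synkin.build_catalog(synkin.PCPool.from_pcsets(pcsets))
        total = sum(c.variance_fraction for c in catalog.clusters)
        assert total == pytest.approx(1.0, abs=1e-12)
        fractions = [c.variance_fraction for c in catalog.clusters]
        assert fractions == sorted(fractions, reverse=True)

    def test_subject_order_does_not_change_cluster_composition(self, small_cohort):
        *_, pcsets = small_cohort
        cat1 = synkin.build_catalog(synkin.PCPool.from_pcsets(pcsets))
        cat2 = synkin.build_catalog(synkin.PCPool.from_pcsets(pcsets[::-1]))
        def sets_of_subjects(cat):
            return sorted(
                sorted(cat.provenance[m] for m in c.members) for c in cat.clusters
            )
        assert sets_of_subjects(cat1) == sets_of_subjects(cat2)

    def test_catalog_json_round_trip(self, small_cohort, tmp_path):
        *_, pcsets = small_cohort
        catalog = synkin.build_catalog(synkin.PCPool.from_pcsets(pcsets))
        path = tmp_path / "catalog.json"
        catalog.to_json(path)
        back = synkin.SynergyCatalog.from_json(path)
        assert back.cut_distance == pytest.approx(catalog.cut_distance)
        assert back.selected == catalog.selected
        for a, b in zip(back.clusters, catalog.clusters):
            assert a.members == b.members
            np.testing.assert_allclose(a.mean_loading, b.mean_loading, atol=1e-12)
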