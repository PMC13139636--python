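import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon, pdist, squareform
from skbio import DistanceMatrix

from enterostrat import (
    calinski_harabasz,
    jensen_shannon_distance,
    jsd_matrix,
    pam_cluster,
    pcoa,
    select_enterotypes,
    simulate_enterotype_dataset,
    EnterotypeSimSpec,
)


class TestJensenShannon:
    def test_identical_distributions_have_zero_distance(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_distance(p, p) == 0.0

    def test_disjoint_supports_reach_sqrt_ln2(self):
        d = jensen_shannon_distance([1.0, 0.0], [0.0, 1.0])
        assert d == pytest.approx(np.sqrt(np.log(2)), abs=1e-12)

    def test_matches_direct_entropy_evaluation(self):
        p, q = np.array([0.5, 0.5]), np.array([0.9, 0.1])
        # independent evaluation straight from the entropy formula
        m = (p + q) / 2

        def h(x):
            x = x[x > 0]
            return -(x * np.log(x)).sum()

        expected = np.sqrt(h(m) - (h(p) + h(q)) / 2)
        assert jensen_shannon_distance(p, q) == pytest.approx(expected, abs=1e-12)
        # and agrees with scipy's implementation (natural log base)
        assert jensen_shannon_distance(p, q) == pytest.approx(
            jensenshannon(p, q), abs=1e-12
        )

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            jensen_shannon_distance([1.2, -0.2], [0.5, 0.5])

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            jensen_shannon_distance([0.5, 0.4], [0.5, 0.5])

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(50):
            p, q, r = (rng.dirichlet(np.ones(6)) for _ in range(3))
            dpq = jensen_shannon_distance(p, q)
            assert dpq == pytest.approx(jensen_shannon_distance(q, p), abs=1e-12)
            assert dpq <= jensen_shannon_distance(p, r) + jensen_shannon_distance(
                r, q
            ) + 1e-12

    def test_matrix_agrees_with_pairwise_calls(self, rng):
        x = rng.dirichlet(np.ones(8), size=5)
        rel = pd.DataFrame(x, index=[f"s{i}" for i in range(5)])
        dm = jsd_matrix(rel)
        for i, j in itertools.combinations(range(5), 2):
            assert dm.data[i, j] == pytest.approx(
                jensen_shannon_distance(x[i], x[j]), abs=1e-9
            )


def _euclid_dm(points):
    ids = [str(i) for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestPam:
    def test_two_blobs_recovered(self, rng):
        pts = np.vstack([rng.normal(0, 0.2, (4, 2)), rng.normal(5, 0.2, (4, 2))])
        labels, medoids, _ = pam_cluster(_euclid_dm(pts), 2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_cost_is_globally_optimal_for_small_n(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 11))
            d = squareform(pdist(rng.normal(size=(n, 2))))
            _, _, cost = pam_cluster(DistanceMatrix(d, ids=[str(i) for i in range(n)]), 2)
            best = min(
                d[:, list(c)].min(axis=1).sum()
                for c in itertools.combinations(range(n), 2)
            )
            assert cost == pytest.approx(best, abs=1e-9)

    def test_heuristic_path_never_beats_nor_crashes(self, rng):
        pts = rng.normal(size=(15, 2))
        dm = _euclid_dm(pts)
        _, _, exact_cost = pam_cluster(dm, 3)
        _, _, heur_cost = pam_cluster(dm, 3, exact=False)
        assert heur_cost >= exact_cost - 1e-9

    def test_k_equals_n_minus_1_leaves_one_pair(self, rng):
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        _, _, cost = pam_cluster(_euclid_dm(pts), 5)
        assert cost == pytest.approx(d[d > 0].min() / 1.0, abs=1e-9)

    def test_out_of_range_k_rejected(self, rng):
        dm = _euclid_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            pam_cluster(dm, 1)
        with pytest.raises(ValueError):
            pam_cluster(dm, 5)

    def test_medoids_are_members_of_their_clusters(self, rng):
        pts = rng.normal(size=(12, 2))
        dm = _euclid_dm(pts)
        labels, medoids, _ = pam_cluster(dm, 3)
        ids = list(dm.ids)
        for c, m in enumerate(medoids, start=1):
            assert labels[ids.index(m)] == c


class TestCalinskiHarabasz:
    def test_equals_classical_formula_on_euclidean_data(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        for _ in range(5):
            pts = rng.normal(size=(25, 3))
            labels = rng.integers(0, 3, 25)
            while len(np.unique(labels)) < 3:
                labels = rng.integers(0, 3, 25)
            ours = calinski_harabasz(_euclid_dm(pts), labels)
            assert ours == pytest.approx(
                calinski_harabasz_score(pts, labels), abs=1e-8
            )

    def test_merging_duplicates_beats_splitting_them(self):
        # 4 points: two coincident pairs; clustering by pair has W = 0
        pts = np.array([[0, 0], [0, 0], [3, 3], [3, 3]], dtype=float)
        dm = _euclid_dm(pts)
        merged = calinski_harabasz(dm, [1, 1, 2, 2])
        split = calinski_harabasz(dm, [1, 2, 1, 2])
        assert merged == np.inf or merged > split


class TestSelectEnterotypes:
    def test_recovers_two_planted_clusters(self):
        spec = EnterotypeSimSpec(n_samples=(15, 10), n_taxa=300, seed=8)
        ct, tax, _, labels = simulate_enterotype_dataset(spec)
        ent = select_enterotypes(ct, tax, k_range=range(2, 5))
        assert ent.chosen_k == 2
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, ent.labels.loc[labels.index]) >= 0.9
        assert ent.chosen_k == min(ent.ch_by_k, key=lambda k: (-ent.ch_by_k[k], k))

    def test_invariant_to_sample_order(self):
        spec = EnterotypeSimSpec(n_samples=(10, 8), n_taxa=150, seed=9)
        ct, tax, _, _ = simulate_enterotype_dataset(spec)
        ent1 = select_enterotypes(ct, tax, k_range=(2, 3))
        rng = np.random.default_rng(0)
        order = rng.permutation(ct.sample_ids)
        from enterostrat import CountTable

        ct2 = CountTable(ct.data.loc[order])
        ent2 = select_enterotypes(ct2, tax, k_range=(2, 3))
        pd.testing.assert_series_equal(
            ent1.labels.sort_index(), ent2.labels.sort_index()
        )


class TestPcoa:
    def test_exactly_recovers_euclidean_configurations(self, rng):
        pts = rng.normal(size=(10, 2))
        res = pcoa(_euclid_dm(pts))
        rec = squareform(pdist(res.coordinates.to_numpy()[:, :2]))
        np.testing.assert_allclose(rec, squareform(pdist(pts)), atol=1e-8)

    def test_eigenvalues_sorted_descending(self, rng):
        pts = rng.normal(size=(8, 3))
        res = pcoa(_euclid_dm(pts))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_first_axis_matches_independent_eigensolver(self, multinomial_table):
        from enterostrat import bray_curtis

        dm = bray_curtis(multinomial_table)
        res = pcoa(dm)
        # independent classical-scaling computation with scipy
        import scipy.linalg

        d2 = np.asarray(dm.data) ** 2
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ d2 @ j
        evals, evecs = scipy.linalg.eigh(g)
        axis1 = evecs[:, -1] * np.sqrt(evals[-1])
        got = res.coordinates.iloc[:, 0].to_numpy()
        assert abs(np.corrcoef(axis1, got)[0, 1]) == pytest.approx(1.0, abs=1e-8)

    def test_proportions_sum_to_at_most_one(self, multinomial_table):
        from enterostrat import bray_curtis

        res = pcoa(bray_curtis(multinomial_table))
        assert res.proportion_explained.sum() <= 1 + 1e-9
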