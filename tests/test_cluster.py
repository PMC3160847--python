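"""Ward agglomeration, tree cutting, k-medoids, 1-D k-means, two-level pipeline."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, is_valid_linkage, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import promshape as ps


def dmat(d, ids=None):
    d = np.asarray(d, dtype=float)
    ids = ids or tuple(str(i) for i in range(d.shape[0]))
    return ps.DissimilarityMatrix(tuple(ids), d)


def random_metric_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    return dmat(squareform(pdist(pts)))


class TestHierarchicalWard:
    def test_two_items_merge_at_their_distance(self):
        dend = ps.hierarchical_ward(dmat([[0, 0.7], [0.7, 0]]))
        assert dend.heights[0] == pytest.approx(0.7)

    def test_nearest_pair_merges_first(self):
        d = dmat([[0, 0.1, 1, 1], [0.1, 0, 1, 1], [1, 1, 0, 0.9], [1, 1, 0.9, 0]])
        dend = ps.hierarchical_ward(d)
        assert set(dend.merges[0, :2]) == {0, 1}

    def test_heights_non_decreasing_on_random_matrices(self, rng):
        for _ in range(50):
            dend = ps.hierarchical_ward(random_metric_matrix(rng, 12))
            assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_linkage_matrix_is_scipy_valid(self, rng):
        dend = ps.hierarchical_ward(random_metric_matrix(rng, 10))
        assert is_valid_linkage(dend.to_scipy())

    def test_squared_dialect_matches_scipy_ward(self, rng):
        # scipy's 'ward' implements the squared-update/root-height dialect
        for _ in range(10):
            m = random_metric_matrix(rng, 11)
            dend = ps.hierarchical_ward(m, dialect="squared")
            Z = linkage(squareform(m.d), method="ward")
            assert np.allclose(np.sort(dend.heights), np.sort(Z[:, 2]))
            for k in (2, 4):
                assert (
                    adjusted_rand_score(
                        ps.cut_dendrogram(dend, k).labels, fcluster(Z, k, "maxclust")
                    )
                    == 1.0
                )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ps.hierarchical_ward(dmat(np.array([[0, 1.0], [2.0, 0]])))


class TestCutDendrogram:
    def test_k_extremes(self, rng):
        m = random_metric_matrix(rng, 7)
        dend = ps.hierarchical_ward(m)
        assert ps.cut_dendrogram(dend, 1).k == 1
        p = ps.cut_dendrogram(dend, 7)
        assert p.k == 7 and len(set(p.labels)) == 7

    def test_k_out_of_range(self, rng):
        dend = ps.hierarchical_ward(random_metric_matrix(rng, 5))
        for k in (0, 6):
            with pytest.raises(ValueError):
                ps.cut_dendrogram(dend, k)

    def test_two_blob_recovery(self, rng):
        pts = np.concatenate([rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2))])
        dend = ps.hierarchical_ward(dmat(squareform(pdist(pts))))
        labels = ps.cut_dendrogram(dend, 2).labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_cuts_are_nested(self, rng):
        dend = ps.hierarchical_ward(random_metric_matrix(rng, 15))
        for k in range(1, 15):
            coarse = ps.cut_dendrogram(dend, k).labels
            fine = ps.cut_dendrogram(dend, k + 1).labels
            # every fine cluster sits inside exactly one coarse cluster
            for c in set(fine):
                assert len({coarse[i] for i in np.flatnonzero(fine == c)}) == 1

    def test_labels_ordered_by_first_leaf(self, rng):
        p = ps.cut_dendrogram(ps.hierarchical_ward(random_metric_matrix(rng, 9)), 4)
        seen = []
        for lab in p.labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)


class TestKMedoids:
    def test_k_equals_n_zero_objective(self, rng):
        m = random_metric_matrix(rng, 6)
        est = ps.KMedoids(n_clusters=6, random_state=0).fit(m)
        assert est.inertia_ == 0.0

    def test_two_blob_recovery_over_seeds(self, rng):
        pts = np.concatenate([rng.normal(0, 0.1, (5, 2)), rng.normal(8, 0.1, (5, 2))])
        m = dmat(squareform(pdist(pts)))
        for seed in range(10):
            p = ps.kmedoids_partition(m, 2, seed=seed)
            assert len(set(p.labels[:5])) == 1
            assert len(set(p.labels[5:])) == 1
            assert p.labels[0] != p.labels[5]

    def test_objective_non_increasing(self, rng):
        m = random_metric_matrix(rng, 20)
        d = m.d
        medoids = np.array([0, 1, 2])
        labels = np.argmin(d[:, medoids], axis=1)
        prev = d[np.arange(20), medoids[labels]].sum()
        for _ in range(10):
            new_medoids = medoids.copy()
            for c in range(3):
                members = np.flatnonzero(labels == c)
                if members.size:
                    within = d[np.ix_(members, members)].sum(axis=1)
                    new_medoids[c] = members[int(np.argmin(within))]
            labels = np.argmin(d[:, new_medoids], axis=1)
            cur = d[np.arange(20), new_medoids[labels]].sum()
            assert cur <= prev + 1e-9
            prev, medoids = cur, new_medoids

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.KMedoids(n_clusters=9).fit(random_metric_matrix(rng, 4))


class TestExplainedVariance:
    def test_one_cluster_zero(self, rng):
        m = random_metric_matrix(rng, 8)
        p = ps.Partition(m.ids, np.ones(8, dtype=int), 1)
        assert ps.explained_variance(m, p) == pytest.approx(0.0)

    def test_all_singletons_one(self, rng):
        m = random_metric_matrix(rng, 8)
        p = ps.Partition(m.ids, np.arange(1, 9), 8)
        assert ps.explained_variance(m, p) == pytest.approx(1.0)

    def test_hand_computed_two_pair_example(self):
        # two tight pairs far apart: d(a,b)=d(c,d)=1, cross distances = 10
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        m = dmat(d)
        p = ps.Partition(m.ids, np.array([1, 1, 2, 2]), 2)
        # T = (1 + 1 + 4*100) / 4 = 100.5 ; W = (1/2 + 1/2) = 1
        assert ps.explained_variance(m, p) == pytest.approx(1 - 1 / 100.5)

    def test_non_decreasing_along_nested_cuts(self, rng):
        m = random_metric_matrix(rng, 14)
        dend = ps.hierarchical_ward(m)
        evs = [
            ps.explained_variance(m, ps.cut_dendrogram(dend, k)) for k in range(1, 15)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(evs, evs[1:]))
        assert all(0 <= ev <= 1 for ev in evs)


def brute_force_1d_kmeans(xs, k):
    """Exhaustive contiguous-split search on the sorted values (the 1-D
    optimum is always contiguous in sorted order)."""
    xs = np.sort(np.asarray(xs, dtype=float))
    n = len(xs)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        sse = sum(
            ((xs[a:b] - xs[a:b].mean()) ** 2).sum() for a, b in zip(bounds, bounds[1:])
        )
        best = min(best, sse)
    return best


class TestKMeans1D:
    def test_three_well_separated_groups_recovered(self):
        scores = [0.01] * 10 + [0.5] * 4 + [1.0] * 3
        part, means = ps.kmeans_1d(scores, 3)
        assert part.k == 3
        labels = part.labels
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:14])) == 1
        assert len(set(labels[14:])) == 1
        assert np.allclose(sorted(means), [0.01, 0.5, 1.0])

    def test_k_one_gives_grand_mean(self, rng):
        x = rng.random(20)
        part, means = ps.kmeans_1d(x, 1)
        assert part.k == 1 and means[0] == pytest.approx(x.mean())

    def test_matches_exhaustive_search(self, rng):
        for _ in range(10):
            x = rng.random(12)
            est = ps.KMeans1D(n_clusters=3).fit(x)
            assert est.inertia_ == pytest.approx(brute_force_1d_kmeans(x, 3), abs=1e-9)

    def test_beats_random_contiguous_splits(self, rng):
        x = np.sort(rng.random(40))
        est = ps.KMeans1D(n_clusters=3).fit(x)
        for _ in range(100):
            cuts = np.sort(rng.choice(np.arange(1, 40), size=2, replace=False))
            bounds = [0, *cuts, 40]
            sse = sum(
                ((x[a:b] - x[a:b].mean()) ** 2).sum()
                for a, b in zip(bounds, bounds[1:])
            )
            assert est.inertia_ <= sse + 1e-12

    def test_clamps_k_to_distinct_values(self):
        with pytest.warns(UserWarning, match="clamping"):
            est = ps.KMeans1D(n_clusters=3).fit([1.0, 1.0, 2.0])
        assert est.n_clusters_ == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ps.KMeans1D().fit([])


class TestTwoLevelClassify:
    def test_class_recovery_on_reference_simulation(self, sim300, fitted300):
        tssds, truth = sim300
        tc = truth.classes()
        labels = {t.id: lab for t, lab in zip(tssds, fitted300.labels_)}
        ari = adjusted_rand_score(
            [tc[t.id] for t in tssds], [labels[t.id] for t in tssds]
        )
        assert ari >= 0.9

    def test_identical_deltas_all_ultra_dense(self):
        tssds = [
            ps.TSSD(f"d{i}", "chr1", "+", 1000 * i, np.array([120])) for i in range(6)
        ]
        mapping, est = ps.two_level_classify(tssds, k1=3, k2=3)
        assert set(mapping.values()) == {"ultra-dense"}

    def test_highest_peakedness_group_is_ultra_dense(self, fitted300):
        est = fitted300
        km_means = {}
        for tier_idx, name in enumerate(est.tier_names_):
            members = np.flatnonzero(est.level2_.labels == tier_idx + 1)
            ids = [est.level2_.ids[i] for i in members]
            km_means[name] = np.mean(
                [est.intra_peakedness_[est.level1_.as_dict()[i] - 1] for i in ids]
            )
        assert km_means["ultra-dense"] == max(km_means.values())
        assert km_means["scattered"] == min(km_means.values())

    def test_order_invariance_up_to_label_names(self, rng):
        tssds, _ = ps.simulate_tssds((8, 8, 8), seed=9)
        mapping_a, _ = ps.two_level_classify(tssds, k1=6, k2=3)
        shuffled = list(tssds)
        rng.shuffle(shuffled)
        mapping_b, _ = ps.two_level_classify(shuffled, k1=6, k2=3)
        assert mapping_a == mapping_b

    def test_k1_clamped_with_warning(self, caplog):
        tssds, _ = ps.simulate_tssds((3, 3, 3), seed=2)
        import logging

        with caplog.at_level(logging.WARNING, logger="promshape.cluster"):
            mapping, est = ps.two_level_classify(tssds, k1=500, k2=3)
        assert est.level1_.k == 9
        assert "clamping" in caplog.text

    def test_too_few_tssds_rejected(self):
        tssds, _ = ps.simulate_tssds((1, 1, 0), seed=2)
        with pytest.raises(ValueError):
            ps.two_level_classify(tssds, k2=3)

    def test_ev_table_monotone(self, fitted300):
        # EV of the 1-D level-2 model over the fitted intra-cluster scores
        scores = fitted300.intra_peakedness_
        total = ((scores - scores.mean()) ** 2).sum()
        evs = [
            1 - ps.KMeans1D(n_clusters=k).fit(scores).inertia_ / total
            for k in range(1, 6)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(evs, evs[1:]))
        # three tiers already explain ~all the peakedness variance
        assert evs[2] >= 0.99
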