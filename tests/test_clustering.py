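"""Clustering procedures: hand values, exhaustive optima, seeding law,
ground-truth recovery, and determinism."""

import numpy as np
import pytest

from decoyclust import (DistanceMatrix, EnsembleSpec, SpickerParams,
                        assign_to_nearest, clustering_objective,
                        generate_decoy_ensemble, kmeans, kmeans_plusplus,
                        kmeans_pp_seed, medoid, pairwise_distances,
                        select_models, sk_means, spicker_cluster)

from oracles import (exhaustive_kmedoids_optimal_centers,
                     exhaustive_kmedoids_optimum, rand_index)


def matrix_from_points(points):
    """1-D point positions -> absolute-difference DistanceMatrix."""
    p = np.asarray(points, dtype=float)
    return DistanceMatrix(np.abs(p[:, None] - p[None, :]), "euclidean")


def random_matrix(rng, n):
    pts = rng.normal(size=(n, 2)) * 5
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix(d, "euclidean")


class TestMedoid:
    def test_singleton_and_hand_instance(self):
        D = matrix_from_points([0.0, 1.0, 2.0])
        assert medoid(D, [2]) == 2
        # pairwise 1,1,2: the middle point minimizes the distance sum
        assert medoid(D, [0, 1, 2]) == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            medoid(matrix_from_points([0.0, 1.0, 2.0]), [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        D = random_matrix(rng, 8)
        members = rng.choice(8, size=rng.integers(1, 9), replace=False)
        best = min(sorted(members),
                   key=lambda i: D.values[i, sorted(members)].sum())
        assert medoid(D, sorted(members)) == best


class TestAssignment:
    def test_single_center_takes_all(self):
        D = matrix_from_points([0, 1, 2, 3])
        assert assign_to_nearest(D, [2]).tolist() == [0, 0, 0, 0]

    def test_all_members_as_centers_is_identity(self):
        D = matrix_from_points([0, 1, 2, 3])
        assert assign_to_nearest(D, [0, 1, 2, 3]).tolist() == [0, 1, 2, 3]

    def test_two_blobs_recover_labels(self, small_labeled, small_rmsd_matrix):
        labels = small_labeled.labels
        centers = [int(np.flatnonzero(labels == k)[0]) for k in range(3)]
        assignment = assign_to_nearest(small_rmsd_matrix, centers)
        assert rand_index(assignment, labels) == 1.0

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError):
            assign_to_nearest(matrix_from_points([0, 1, 2]), [1, 1])


class TestKMeans:
    def test_identical_members_converge_to_zero_objective(self):
        D = DistanceMatrix(np.zeros((5, 5)), "rmsd")
        result = kmeans(D, [0, 1])
        assert result.n_iterations <= 2
        assert clustering_objective(D, result.assignment,
                                    result.center_indices) == 0.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans(matrix_from_points([0, 1]), [0, 1, 1])

    def test_two_blob_recovery_with_good_seeds(self):
        spec = EnsembleSpec(n_residues=30, cluster_sizes=(15, 10),
                            cluster_noise=(0.4, 0.4),
                            cluster_offsets=((0, 0), (60, 12)), seed=11)
        labeled = generate_decoy_ensemble(spec)
        D = pairwise_distances(labeled.ensemble, "rmsd")
        seeds = [int(np.flatnonzero(labeled.labels == k)[0]) for k in range(2)]
        result = kmeans(D, seeds)
        assert rand_index(result.assignment, labeled.labels) == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_never_beats_exhaustive_optimum_and_attains_it_when_seeded(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 9))
        K = int(rng.integers(2, 4))
        D = random_matrix(rng, n)
        opt, opt_centers = exhaustive_kmedoids_optimal_centers(D.values, K)
        # any seeding: final objective is bounded below by the optimum
        seeds = rng.choice(n, size=K, replace=False)
        result = kmeans(D, seeds)
        obj = clustering_objective(D, result.assignment, result.center_indices)
        assert obj >= opt - 1e-9
        # optimal seeding: the optimum is a fixed point of the descent
        seeded = kmeans(D, list(opt_centers))
        obj_seeded = clustering_objective(D, seeded.assignment,
                                          seeded.center_indices)
        assert obj_seeded == pytest.approx(opt, abs=1e-9)

    def test_objective_nonincreasing_trace(self):
        # descent property checked step-by-step on a moderate instance
        rng = np.random.default_rng(3)
        D = random_matrix(rng, 40)
        centers = list(rng.choice(40, size=4, replace=False))
        prev = np.inf
        for _ in range(20):
            assignment = assign_to_nearest(D, centers)
            obj = clustering_objective(D, assignment, np.array(centers))
            assert obj <= prev + 1e-9
            prev = obj
            new_centers = [medoid(D, np.flatnonzero(assignment == k))
                           for k in range(4)]
            if new_centers == centers:
                break
            centers = new_centers


class TestKMeansPPSeed:
    def test_k1_uniform(self):
        D = matrix_from_points([0, 1, 2])
        draws = {kmeans_pp_seed(D, 1, np.random.default_rng(s))[0]
                 for s in range(60)}
        assert draws == {0, 1, 2}

    def test_three_point_seeding_law(self):
        # d(A,B)=1, d(A,C)=10: with first center A, P(C) = 100/101
        values = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 9.0], [10.0, 9.0, 0.0]])
        D = DistanceMatrix(values, "euclidean")
        n, hits = 20000, 0
        count = 0
        for s in range(10 * n):
            rng = np.random.default_rng(s)
            centers = kmeans_pp_seed(D, 2, rng)
            if centers[0] != 0:
                continue  # condition on the first center being A
            count += 1
            hits += centers[1] == 2
            if count == n:
                break
        p_hat = hits / n
        p = 100.0 / 101.0
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) <= 3 * se

    def test_second_center_mass_lands_in_other_blob(self):
        # two 1-D blobs; enumerate the squared-distance mass directly
        points = [0.0, 0.1, 0.2, 10.0, 10.1]
        D = matrix_from_points(points)
        n, hits, count = 5000, 0, 0
        for s in range(100 * n):
            rng = np.random.default_rng(s)
            centers = kmeans_pp_seed(D, 2, rng)
            if centers[0] != 0:
                continue
            count += 1
            hits += centers[1] in (3, 4)
            if count == n:
                break
        d2 = np.array([0.0, 0.01, 0.04, 100.0, 102.01])
        p = d2[3:].sum() / d2.sum()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) <= 3 * se

    def test_zero_distance_members_never_rechosen(self):
        # duplicated points: mass at a chosen center's duplicates is zero
        values = np.zeros((4, 4))
        values[0:2, 2:4] = 5.0
        values[2:4, 0:2] = 5.0
        D = DistanceMatrix(values, "rmsd")
        for s in range(30):
            centers = kmeans_pp_seed(D, 2, np.random.default_rng(s))
            assert {centers[0] // 2, centers[1] // 2} == {0, 1}

    def test_fallback_when_all_masses_zero(self):
        D = DistanceMatrix(np.zeros((3, 3)), "rmsd")
        centers = kmeans_pp_seed(D, 3, np.random.default_rng(0))
        assert sorted(centers) == [0, 1, 2]


class TestSpicker:
    def test_one_tight_cluster(self):
        rng = np.random.default_rng(0)
        D = DistanceMatrix(np.abs(rng.normal(size=(6, 1)) * 0.0
                                  + np.zeros((6, 6))), "rmsd")
        result = spicker_cluster(D)
        assert result.k == 1
        assert result.sizes().tolist() == [6]

    def test_two_blobs_recover_labels(self):
        # blob gap (>5 A) far above the cutoff ceiling (4 A): neighborhoods
        # cannot leak across blobs
        spec = EnsembleSpec(n_residues=30, cluster_sizes=(12, 8),
                            cluster_noise=(0.4, 0.4),
                            cluster_offsets=((0, 0), (80, 15)), seed=5)
        labeled = generate_decoy_ensemble(spec)
        D = pairwise_distances(labeled.ensemble, "rmsd")
        params = SpickerParams(initial_cutoff=3.0, cutoff_min=1.5, cutoff_max=4.0)
        result = spicker_cluster(D, params)
        assert result.k == 2
        assert rand_index(result.assignment, labeled.labels) == 1.0
        # clusters ordered by decreasing size
        assert result.sizes().tolist() == [12, 8]

    def test_cutoff_monotonicity(self, small_rmsd_matrix):
        V = small_rmsd_matrix.values
        sizes = [int((V <= c).sum(axis=1).max()) for c in (2.0, 4.0, 8.0, 12.0)]
        assert sizes == sorted(sizes)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SpickerParams(initial_cutoff=2.0)  # below cutoff_min
        with pytest.raises(ValueError):
            SpickerParams(target_fraction_range=(0.7, 0.2))


class TestSkMeans:
    def test_perfectly_clustered_data_is_a_fixed_point(self, small_labeled,
                                                       small_rmsd_matrix):
        result = sk_means(small_rmsd_matrix)
        assert result.n_iterations <= 2
        assert rand_index(result.assignment, small_labeled.labels) == 1.0
        assert result.seed_method == "spicker"

    def test_refinement_never_worsens_spicker_partition(self):
        spec = EnsembleSpec(n_residues=40, cluster_sizes=(20, 15, 10),
                            cluster_noise=(1.2, 1.2, 1.2), seed=9)
        labeled = generate_decoy_ensemble(spec)
        D = pairwise_distances(labeled.ensemble, "rmsd")
        initial = spicker_cluster(D)
        initial_obj = clustering_objective(
            D, initial.assignment,
            np.array([medoid(D, initial.members_of(k)) for k in range(initial.k)]))
        refined = sk_means(D)
        refined_obj = clustering_objective(D, refined.assignment,
                                           refined.center_indices)
        assert refined_obj <= initial_obj + 1e-9

    def test_three_blob_label_recovery(self, small_labeled, small_rmsd_matrix):
        result = sk_means(small_rmsd_matrix)
        assert result.k == 3
        assert rand_index(result.assignment, small_labeled.labels) == 1.0


class TestKMeansPlusPlus:
    def test_k_equals_n_zero_objective(self):
        D = matrix_from_points([0, 1, 2, 3])
        result = kmeans_plusplus(D, K=4, rng=np.random.default_rng(0))
        obj = clustering_objective(D, result.assignment, result.center_indices)
        assert obj == 0.0 and result.k == 4

    def test_seeding_beats_uniform_on_two_blobs(self):
        spec = EnsembleSpec(n_residues=30, cluster_sizes=(25, 5),
                            cluster_noise=(0.6, 0.6),
                            cluster_offsets=((0, 0), (70, 14)), seed=21)
        labeled = generate_decoy_ensemble(spec)
        D = pairwise_distances(labeled.ensemble, "rmsd")
        pp_wins = unif_wins = 0
        for s in range(100):
            pp = kmeans_plusplus(D, K=2, rng=np.random.default_rng(s))
            pp_wins += rand_index(pp.assignment, labeled.labels) == 1.0
            rng = np.random.default_rng(s)
            seeds = rng.choice(D.n, size=2, replace=False)
            un = kmeans(D, seeds)
            unif_wins += rand_index(un.assignment, labeled.labels) == 1.0
        assert pp_wins >= unif_wins

    def test_fixed_seed_reproducible_in_process(self, small_rmsd_matrix):
        a = kmeans_plusplus(small_rmsd_matrix, K=3, rng=np.random.default_rng(7))
        b = kmeans_plusplus(small_rmsd_matrix, K=3, rng=np.random.default_rng(7))
        assert np.array_equal(a.assignment, b.assignment)
        assert np.array_equal(a.center_indices, b.center_indices)


class TestSelectModels:
    def test_single_cluster_returns_global_medoid(self):
        D = matrix_from_points([0, 1, 2, 3, 10])
        result = kmeans(D, [0])
        assert select_models(result, D) == [medoid(D, range(5))]

    def test_model1_comes_from_largest_cluster(self, small_labeled,
                                               small_rmsd_matrix):
        result = sk_means(small_rmsd_matrix)
        models = select_models(result, small_rmsd_matrix, n_models=3)
        top = np.argmax(result.sizes())
        assert result.assignment[models[0]] == top
        assert len(models) == 3

    def test_equal_size_tie_broken_by_compactness(self):
        # two 3-member clusters, the second tighter
        pts = [0.0, 1.0, 2.0, 10.0, 10.1, 10.2]
        D = matrix_from_points(pts)
        result = kmeans(D, [1, 4])
        models = select_models(result, D, n_models=2)
        sub0 = D.values[np.ix_([0, 1, 2], [0, 1, 2])]
        sub1 = D.values[np.ix_([3, 4, 5], [3, 4, 5])]
        assert sub1.mean() < sub0.mean()
        assert models[0] == 4  # the tighter cluster ranks first


class TestDeterminism:
    def test_all_methods_bit_identical_across_runs(self, small_rmsd_matrix):
        D = small_rmsd_matrix
        for build in (lambda: sk_means(D),
                      lambda: spicker_cluster(D),
                      lambda: kmeans_plusplus(D, K=3, rng=np.random.default_rng(3)),
                      lambda: kmeans(D, [0, 10, 20])):
            a, b = build(), build()
            assert np.array_equal(a.assignment, b.assignment)
            assert np.array_equal(a.center_indices, b.center_indices)
            assert a.n_iterations == b.n_iterations
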