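import json

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import iainmap as im
from iainmap.iain import (
    IainConfig,
    candidate_radius,
    clone_and_mutate,
    commit_best_antibody,
    normalize_apply,
    normalize_fit,
    preselect,
)


class TestNormalization:
    def test_fit_bounds_are_min_max(self):
        X = np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]])
        lo, hi = normalize_fit(X)
        np.testing.assert_allclose(lo, [2, 5])
        np.testing.assert_allclose(hi, [6, 5])

    def test_apply_scales_clips_and_handles_degenerate(self):
        bounds = (np.array([2.0, 5.0]), np.array([6.0, 5.0]))
        out = normalize_apply(np.array([[4.0, 7.0], [8.0, 5.0]]), bounds)
        np.testing.assert_allclose(out[0], [0.5, 0.5])  # degenerate -> 0.5
        assert out[1, 0] == 1.0  # clipped above

    def test_missing_entries_stay_missing(self):
        bounds = (np.zeros(2), np.ones(2))
        out = normalize_apply(np.array([[0.3, np.nan]]), bounds)
        assert out[0, 0] == pytest.approx(0.3) and np.isnan(out[0, 1])

    def test_empty_or_incomplete_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_fit(np.empty((0, 3)))
        with pytest.raises(ValueError):
            normalize_fit(np.array([[1.0, np.nan]]))


class TestCandidateRadius:
    def test_three_four_five_distance(self):
        X = np.array([[0.0, 0.0], [0.6, 0.8]])
        y = np.array(["a", "b"], dtype=object)
        eps = 1e-6
        r = candidate_radius(X[0], X, y, "a", eps)
        assert r == pytest.approx(1.0 - eps)

    def test_single_class_fallback_is_cube_diagonal(self):
        X = np.random.default_rng(0).random((5, 4))
        y = np.array(["a"] * 5, dtype=object)
        assert candidate_radius(X[0], X, y, "a") == pytest.approx(2.0)

    def test_coincident_other_class_floors_at_zero(self):
        X = np.array([[0.5, 0.5], [0.5, 0.5]])
        y = np.array(["a", "b"], dtype=object)
        assert candidate_radius(X[0], X, y, "a") == 0.0


class TestPreselect:
    def test_single_remaining_antigen(self):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        y = np.array(["a", "b"], dtype=object)
        unrec = np.array([False, True])
        assert preselect(X, y, unrec) == 1

    def test_cluster_member_beats_outlier_brute_force(self):
        rng = np.random.default_rng(1)
        cluster = 0.2 + 0.01 * rng.random((5, 2))
        outlier = np.array([[0.45, 0.05]])
        other = np.array([[0.5, 0.95], [0.6, 0.9]])
        X = np.vstack([cluster, outlier, other])
        y = np.array(["a"] * 6 + ["b"] * 2, dtype=object)
        unrec = np.ones(8, dtype=bool)
        picked = preselect(X, y, unrec)
        # independent brute-force count of same-label coverage
        counts = []
        for i in range(8):
            r = candidate_radius(X[i], X, y, y[i])
            d = np.linalg.norm(X - X[i], axis=1)
            counts.append(((y == y[i]) & (d <= r) & unrec).sum())
        assert picked == int(np.argmax(counts))
        assert picked < 5  # a cluster member

    def test_tie_breaks_to_lowest_index(self):
        X = np.array([[0.2, 0.2], [0.2, 0.2], [0.9, 0.9]])
        y = np.array(["a", "a", "b"], dtype=object)
        assert preselect(X, y, np.array([True, True, True])) == 0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            preselect(np.zeros((2, 2)), np.array(["a", "b"]), np.zeros(2, bool))


class TestCloneAndMutate:
    def test_original_included_and_count(self):
        rng = np.random.default_rng(2)
        cfg = IainConfig(n_clones=10, mutation_sigma=0.05)
        out = clone_and_mutate(np.array([0.5, 0.5]), cfg, rng)
        assert out.shape == (11, 2)
        np.testing.assert_array_equal(out[0], [0.5, 0.5])

    def test_zero_sigma_collapses_to_original(self):
        rng = np.random.default_rng(3)
        cfg = IainConfig(n_clones=5, mutation_sigma=0.0)
        out = clone_and_mutate(np.array([0.3, 0.7]), cfg, rng)
        np.testing.assert_array_equal(out, np.tile([0.3, 0.7], (6, 1)))

    def test_candidates_clipped_to_unit_cube(self):
        rng = np.random.default_rng(4)
        cfg = IainConfig(n_clones=50, mutation_sigma=0.5)
        out = clone_and_mutate(np.array([0.02, 0.98]), cfg, rng)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestCommitBestAntibody:
    def test_isolated_antigen_recognized_alone(self):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        y = np.array(["a", "b"], dtype=object)
        unrec = np.ones(2, dtype=bool)
        ab, cover = commit_best_antibody(X[0:1], X, y, unrec, "a")
        assert ab.label == "a" and cover.tolist() == [True, False]

    def test_shifted_candidate_covering_more_wins(self):
        # original 'a' antigen isolated at 0.0; 'b' blocker at 0.35 caps its
        # radius; a candidate shifted into the cluster covers three antigens
        X = np.array([[0.0], [0.4], [0.45], [0.5], [0.35]])
        y = np.array(["a", "a", "a", "a", "b"], dtype=object)
        unrec = np.array([True, True, True, True, False])
        candidates = np.array([[0.0], [0.45]])
        ab, cover = commit_best_antibody(candidates, X, y, unrec, "a")
        assert ab.center[0] == pytest.approx(0.45)
        assert cover.sum() == 3

    def test_tie_prefers_unmutated_original(self):
        X = np.array([[0.2, 0.2], [0.9, 0.9]])
        y = np.array(["a", "b"], dtype=object)
        unrec = np.array([True, False])
        candidates = np.array([[0.2, 0.2], [0.21, 0.2]])  # both cover only row 0
        ab, _ = commit_best_antibody(candidates, X, y, unrec, "a")
        np.testing.assert_array_equal(ab.center, [0.2, 0.2])


class TestTrain:
    def test_singleton_classes_get_one_antibody_each(self):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        net = im.train(X, ["a", "b"], IainConfig(seed=0))
        assert sorted(ab.label for ab in net.antibodies) == ["a", "b"]
        pred, _ = net.classify_matrix(X)
        assert pred.tolist() == ["a", "b"]

    def test_every_antigen_recognized_by_own_label(self, two_class_gaussian):
        X, y, _, _ = two_class_gaussian
        net = im.train(X, y, IainConfig(seed=5))
        Z = normalize_apply(X, (net.bounds_min, net.bounds_max))
        for i in range(len(y)):
            covered = any(
                ab.label == y[i]
                and np.linalg.norm(Z[i] - ab.center) <= ab.radius + 1e-12
                for ab in net.antibodies
            )
            assert covered

    def test_training_set_accuracy_100(self, two_class_gaussian):
        X, y, _, _ = two_class_gaussian
        net = im.train(X, y, IainConfig(seed=5))
        pred, bad = net.classify_matrix(X)
        assert not bad.any() and (pred == y).all()

    def test_antibody_count_bounded_by_antigen_count(self, two_class_gaussian):
        X, y, _, _ = two_class_gaussian
        net = im.train(X, y, IainConfig(seed=5))
        assert 1 <= len(net.antibodies) <= len(y)

    def test_same_seed_identical_network(self, two_class_gaussian):
        X, y, _, _ = two_class_gaussian
        a = im.train(X, y, IainConfig(seed=9))
        b = im.train(X, y, IainConfig(seed=9))
        assert a.to_json() == b.to_json()

    def test_missing_training_vectors_rejected(self):
        X = np.array([[0.1, np.nan], [0.9, 0.9]])
        with pytest.raises(ValueError, match="missing"):
            im.train(X, ["a", "b"])

    def test_conflicting_duplicate_labels_warn_and_keep_both(self):
        X = np.array([[0.5, 0.5], [0.5, 0.5], [0.1, 0.1], [0.9, 0.9]])
        y = ["a", "b", "a", "b"]
        with pytest.warns(UserWarning, match="conflicting"):
            net = im.train(X, y, IainConfig(seed=0))
        zero_radius = [ab for ab in net.antibodies if ab.radius == 0.0]
        assert len(zero_radius) >= 2

    def test_nearest_prototype_oracle_with_zero_mutation(self, two_class_gaussian):
        """With mutation off, classification is 1-NN over committed antigens."""
        X, y, Xte, _ = two_class_gaussian
        net = im.train(X, y, IainConfig(seed=5, mutation_sigma=0.0, radius_epsilon=0.0))
        Z = normalize_apply(X, (net.bounds_min, net.bounds_max))
        centers = np.vstack([ab.center for ab in net.antibodies])
        # committed centers are actual (normalized) training antigens
        assert cdist(centers, Z).min(axis=1).max() == 0.0
        labels = np.array([ab.label for ab in net.antibodies], dtype=object)
        Zte = normalize_apply(Xte, (net.bounds_min, net.bounds_max))
        oracle = labels[np.argmin(cdist(Zte, centers), axis=1)]
        pred, _ = net.classify_matrix(Xte)
        assert (pred == oracle).all()


class TestClassify:
    @pytest.fixture()
    def toy_net(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        return im.train(X, ["a", "b"], IainConfig(seed=0))

    def test_sub_antibody_restriction(self, toy_net):
        label, dist, _ = toy_net.classify(np.array([0.1, np.nan]))
        assert label == "a" and dist == pytest.approx(0.1)

    def test_complete_query_matches_unmasked(self, two_class_gaussian):
        X, y, Xte, _ = two_class_gaussian
        net = im.train(X, y, IainConfig(seed=5))
        for v in Xte[:20]:
            full = net.classify(v)[0]
            # identical availability mask (all present) must agree trivially,
            # checked against a direct full-space distance computation
            Z = normalize_apply(v[None, :], (net.bounds_min, net.bounds_max))[0]
            d = [np.linalg.norm(Z - ab.center) for ab in net.antibodies]
            assert full == net.antibodies[int(np.argmin(d))].label

    def test_equidistant_tie_goes_to_earliest_antibody(self, toy_net):
        label, _, _ = toy_net.classify(np.array([0.5, 0.5]))
        assert label == toy_net.antibodies[0].label

    def test_all_missing_is_unclassifiable(self, toy_net):
        with pytest.raises(im.UnclassifiableError):
            toy_net.classify(np.array([np.nan, np.nan]))

    def test_masking_consistency_at_center_coordinate(self, toy_net):
        # feature 1 equals antibody a's center there; masking it cannot
        # change the label while the margin dominates
        v = np.array([0.1, 0.0])
        masked = np.array([0.1, np.nan])
        assert toy_net.classify(v)[0] == toy_net.classify(masked)[0] == "a"


class TestSerialization:
    def test_json_round_trip_exact(self, two_class_gaussian):
        X, y, Xte, _ = two_class_gaussian
        net = im.train(X, y, IainConfig(seed=5))
        back = im.AntibodyNetwork.from_json(net.to_json())
        assert back.to_json() == net.to_json()
        p1, _ = net.classify_matrix(Xte)
        p2, _ = back.classify_matrix(Xte)
        assert (p1 == p2).all()

    def test_save_load_file(self, two_class_gaussian, tmp_path):
        X, y, _, _ = two_class_gaussian
        net = im.train(X, y, IainConfig(seed=1))
        path = tmp_path / "model.json"
        net.save(path)
        assert im.AntibodyNetwork.load(path).to_json() == net.to_json()
        json.loads(path.read_text())  # valid JSON on disk


class TestClassifyCube:
    def test_matches_rowwise_classify_and_flags_empty_pixels(self, small_cube):
        labels = ["a", "a", "b"]
        complete = ~small_cube.missing.any(axis=1)
        assert complete.all()
        net = im.train_cube(small_cube, labels, IainConfig(seed=0))
        pred, bad = im.classify_cube(net, small_cube)
        assert not bad.any()
        for i in range(small_cube.n_pixels):
            assert pred[i] == net.classify(small_cube.values[i])[0]

    def test_absent_manifest_features_treated_as_missing(self, small_cube):
        net = im.train_cube(small_cube, ["a", "a", "b"], IainConfig(seed=0))
        sub = small_cube.select_features([0, 1])
        pred, bad = im.classify_cube(net, sub)
        assert not bad.any() and set(pred) <= {"a", "b"}

    def test_permutation_equivariance(self, small_cube):
        net = im.train_cube(small_cube, ["a", "a", "b"], IainConfig(seed=0))
        perm = np.array([2, 0, 1])
        pred, _ = im.classify_cube(net, small_cube)
        pred_p, _ = im.classify_cube(net, small_cube.select_pixels(perm))
        assert (pred_p == pred[perm]).all()
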