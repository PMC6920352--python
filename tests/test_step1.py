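"""Step 1: clustering, assignment, impact scores — against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from keyfeat import step1_features as s1


def _profile(labels_k, is_pos, k, background=None):
    a = s1.Assignment(np.asarray(labels_k), np.zeros(len(labels_k)), k)
    return a, s1.compute_impact_profile(a, np.asarray(is_pos, bool), background)


class TestFitClusters:
    def test_k_distinct_points_become_centroids(self):
        pts = np.array([[0., 0], [10, 0], [0, 10]])
        model = s1.fit_clusters(pts, 3, seed=0, n_init=2)
        found = {tuple(c) for c in np.round(model.centroids, 6)}
        assert found == {(0., 0.), (10., 0.), (0., 10.)}

    def test_k1_centroid_is_mean(self):
        pts = np.random.default_rng(0).normal(size=(20, 4))
        model = s1.fit_clusters(pts, 1, seed=0, n_init=1)
        assert np.allclose(model.centroids[0], pts.mean(axis=0))

    def test_two_means_matches_exhaustive_partition(self):
        """Compare against the optimal 2-partition by enumerating all splits."""
        rng = np.random.default_rng(2)
        pts = np.concatenate([rng.normal(0, 1, (6, 2)),
                              rng.normal(8, 1, (6, 2))])

        def ssq(mask):
            a, b = pts[mask], pts[~mask]
            return (((a - a.mean(0)) ** 2).sum() if len(a) else 0.0) + \
                   (((b - b.mean(0)) ** 2).sum() if len(b) else 0.0)

        best = min((m for i in range(1, 2 ** 12 - 1)
                    for m in [np.array(list(np.binary_repr(i, 12))) == "1"]
                    if 0 < m.sum() < 12), key=ssq)
        model = s1.fit_clusters(pts, 2, seed=0)
        got = s1.assign(pts, model).labels
        same = (got == got[np.argmax(best)])
        assert np.array_equal(same, best) or np.array_equal(same, ~best)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="smaller K"):
            s1.fit_clusters(np.zeros((3, 2)), 5)

    def test_model_round_trips_through_file(self, tmp_path):
        model = s1.ClusterModel(np.arange(6.).reshape(3, 2), seed=1,
                                background={2})
        model.save(tmp_path / "m.npz")
        loaded = s1.ClusterModel.load(tmp_path / "m.npz")
        assert np.array_equal(loaded.centroids, model.centroids)
        assert loaded.background == {2}


class TestAssign:
    def test_code_at_centroid_has_zero_distance(self):
        model = s1.ClusterModel(np.eye(8) * 5, seed=0)
        a = s1.assign(np.eye(8)[7:8] * 5, model)
        assert a.labels[0] == 7 and a.distances[0] == pytest.approx(0.0)

    def test_one_hot_partition(self):
        rng = np.random.default_rng(1)
        model = s1.ClusterModel(rng.normal(size=(4, 3)), seed=0)
        a = s1.assign(rng.normal(size=(25, 3)), model)
        assert np.array_equal(a.one_hot().sum(axis=1), np.ones(25))

    def test_matches_brute_force_nearest_search(self):
        rng = np.random.default_rng(3)
        codes = rng.normal(size=(10, 5))
        model = s1.ClusterModel(rng.normal(size=(3, 5)), seed=0)
        a = s1.assign(codes, model)
        for i, code in enumerate(codes):
            dists = [np.linalg.norm(code - c) for c in model.centroids]
            assert a.labels[i] == int(np.argmin(dists))
            assert a.distances[i] == pytest.approx(min(dists))

    def test_ties_break_to_smallest_index(self):
        model = s1.ClusterModel(np.array([[1., 0], [-1, 0]]), seed=0)
        a = s1.assign(np.array([[0., 5]]), model)
        assert a.labels[0] == 0

    def test_dimension_mismatch_rejected(self):
        model = s1.ClusterModel(np.zeros((2, 3)), seed=0)
        with pytest.raises(ValueError, match="width"):
            s1.assign(np.zeros((4, 5)), model)


class TestImpactProfile:
    def test_hand_computed_degrees_and_impact(self):
        # 10 positive patches, 4 in feature 0; 20 negative, 2 in feature 0
        labels = [0] * 4 + [1] * 6 + [0] * 2 + [1] * 18
        is_pos = [True] * 10 + [False] * 20
        _, prof = _profile(labels, is_pos, 2)
        assert prof.r_positive[0] == pytest.approx(0.4)
        assert prof.r_negative[0] == pytest.approx(0.1)
        assert prof.impact[0] == pytest.approx(0.8)

    def test_symmetric_degrees_give_half(self):
        _, prof = _profile([0, 0, 1, 1], [True, False, True, False], 2)
        assert np.allclose(prof.impact, 0.5)

    def test_positive_only_feature_scores_one(self):
        _, prof = _profile([0, 1, 1], [True, False, False], 2)
        assert prof.impact[0] == 1.0

    def test_empty_feature_is_undefined_not_half(self):
        _, prof = _profile([0, 1], [True, False], 3)
        assert np.isnan(prof.impact[2])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="both outcome groups"):
            _profile([0, 1], [True, True], 2)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 4), min_size=8, max_size=40),
           st.integers(0, 2 ** 30))
    def test_partition_conservation_and_range(self, labels_k, seed):
        """Sum of degrees is 1 per group; defined impacts lie in [0, 1]."""
        rng = np.random.default_rng(seed)
        is_pos = rng.random(len(labels_k)) < 0.5
        if is_pos.all() or not is_pos.any():
            is_pos[0] = True
            is_pos[-1] = False
        _, prof = _profile(labels_k, is_pos, 5)
        assert prof.r_positive.sum() == pytest.approx(1.0)
        assert prof.r_negative.sum() == pytest.approx(1.0)
        defined = ~np.isnan(prof.impact)
        assert ((prof.impact[defined] >= 0) & (prof.impact[defined] <= 1)).all()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 30))
    def test_label_swap_antisymmetry(self, seed):
        """Exchanging outcome groups maps I_k to exactly 1 - I_k."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, 30)
        is_pos = rng.random(30) < 0.4
        if is_pos.all() or not is_pos.any():
            is_pos[:2] = [True, False]
        _, prof = _profile(labels, is_pos, 4)
        _, swapped = _profile(labels, ~is_pos, 4)
        defined = ~np.isnan(prof.impact)
        assert np.allclose(swapped.impact[defined], 1 - prof.impact[defined])

    def test_background_features_stay_undefined_and_unweighted(self):
        _, prof = _profile([0, 0, 1, 1], [True, False, True, False], 2,
                           background={1})
        assert np.isnan(prof.impact[1])
        assert prof.weights()[1] == 1.0


class TestPatchImpact:
    def test_lookup_equals_explicit_sum(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 5, 100)
        is_pos = rng.random(100) < 0.5
        is_pos[:2] = [True, False]
        a, prof = _profile(labels, is_pos, 5)
        scores = s1.patch_impact(a, prof)
        u = a.one_hot()
        impact = np.where(np.isnan(prof.impact), 0.0, prof.impact)
        explicit = u @ impact
        defined = ~np.isnan(scores)
        assert np.allclose(scores[defined], explicit[defined])

    def test_all_neutral_features_score_half(self):
        a, prof = _profile([0, 1, 0, 1], [True, True, False, False], 2)
        assert np.allclose(s1.patch_impact(a, prof), 0.5)

    def test_background_patch_is_unscored(self):
        a, prof = _profile([0, 1, 0, 1], [True, True, False, False], 2,
                           background={1})
        scores = s1.patch_impact(a, prof)
        assert np.isnan(scores[1]) and not np.isnan(scores[0])


class TestBackgroundFlagging:
    def _model_and_assignment(self, patches):
        model = s1.ClusterModel(np.zeros((2, 1)), seed=0)
        labels = np.array([0] * (len(patches) // 2)
                          + [1] * (len(patches) - len(patches) // 2))
        return model, s1.Assignment(labels, np.zeros(len(patches)), 2)

    def test_white_cluster_flagged(self):
        white = np.full((4, 8, 8, 3), 250, np.uint8)
        tissue = np.full((4, 8, 8, 3), 120, np.uint8)
        patches = np.concatenate([white, tissue])
        model, a = self._model_and_assignment(patches)
        flagged = s1.flag_background_clusters(model, patches, a)
        assert flagged == {0} and model.background == {0}

    def test_no_white_patches_means_empty_set(self):
        patches = np.full((8, 8, 8, 3), 100, np.uint8)
        model, a = self._model_and_assignment(patches)
        assert s1.flag_background_clusters(model, patches, a) == set()

    def test_saturated_bright_cluster_not_flagged(self):
        bright = np.zeros((8, 8, 8, 3), np.uint8)
        bright[..., 0] = 255  # bright but saturated red
        model, a = self._model_and_assignment(bright)
        assert s1.flag_background_clusters(model, bright, a) == set()


class TestRepresentatives:
    def test_ranking_equals_full_sort_of_member_distances(self):
        rng = np.random.default_rng(5)
        model = s1.ClusterModel(rng.normal(size=(3, 4)), seed=0)
        codes = rng.normal(size=(40, 4))
        a = s1.assign(codes, model)
        reps = s1.select_representatives(model, a, top_n=5)
        for k, idx in reps.items():
            members = np.flatnonzero(a.labels == k)
            expect = members[np.argsort(a.distances[members], kind="stable")][:5]
            assert np.array_equal(idx, expect)

    def test_injected_centroid_code_ranks_first(self):
        rng = np.random.default_rng(6)
        model = s1.ClusterModel(rng.normal(size=(2, 3)), seed=0)
        codes = np.vstack([rng.normal(size=(10, 3)), model.centroids[1]])
        a = s1.assign(codes, model)
        reps = s1.select_representatives(model, a, top_n=3)
        assert reps[1][0] == 10
        assert a.distances[10] == pytest.approx(0.0)

    def test_single_member_feature_and_background_skipped(self):
        model = s1.ClusterModel(np.array([[0.], [10.]]), seed=0,
                                background={1})
        a = s1.assign(np.array([[0.1], [10.2], [9.9]]), model)
        reps = s1.select_representatives(model, a)
        assert list(reps) == [0]
        assert np.array_equal(reps[0], [0])
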