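import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from netdc import mvpa
from netdc.errors import InputError
from netdc.images import VolumeMap


def separable_features(rng, n_per_class=10, n_voxels=30, gap=8.0):
    """Two distant Gaussian clouds: patients shifted by ``gap`` on all voxels."""
    x = rng.standard_normal((2 * n_per_class, n_voxels))
    x[:n_per_class] += gap
    y = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    return mvpa.FeatureMatrix(x=x, y=y, voxel_index=np.arange(n_voxels))


class TestConfusionMetrics:
    @given(tp=st.integers(0, 50), fn=st.integers(0, 50),
           tn=st.integers(0, 50), fp=st.integers(0, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identities_hold_exactly(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = mvpa.confusion_metrics(tp, fn, tn, fp)
        assert m["accuracy"] == 100.0 * (tp + tn) / (tp + fn + tn + fp)
        assert m["sensitivity"] == 100.0 * tp / (tp + fn)
        assert m["specificity"] == 100.0 * tn / (tn + fp)

    def test_one_class_absent_rejected(self):
        with pytest.raises(InputError):
            mvpa.confusion_metrics(0, 0, 10, 5)


class TestBuildFeatureMatrix:
    def _maps(self, values):
        return [VolumeMap(data=np.asarray(v, dtype=float).reshape(3, 1, 1),
                          affine=np.eye(4), kind="dc_z") for v in values]

    def test_values_land_in_scan_order(self):
        maps = self._maps([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        mask = np.ones((3, 1, 1), dtype=bool)
        fm = mvpa.build_feature_matrix(maps, mask, ["patient", "control"])
        np.testing.assert_array_equal(fm.x, [[1, 2, 3], [4, 5, 6]])
        np.testing.assert_array_equal(fm.y, [1, 0])

    def test_deterministic_repeat(self):
        maps = self._maps([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        mask = np.ones((3, 1, 1), dtype=bool)
        a = mvpa.build_feature_matrix(maps, mask, ["patient", "control"])
        b = mvpa.build_feature_matrix(maps, mask, ["patient", "control"])
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.voxel_index, b.voxel_index)

    def test_nan_inside_mask_rejected(self):
        maps = self._maps([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0]])
        mask = np.ones((3, 1, 1), dtype=bool)
        with pytest.raises(InputError, match="NaN"):
            mvpa.build_feature_matrix(maps, mask, ["patient", "control"])


class TestLoocv:
    def test_separable_clouds_classify_perfectly(self, rng):
        cv = mvpa.loocv_classify(separable_features(rng))
        assert cv.accuracy == 100.0
        assert cv.auc == 1.0
        assert cv.n_folds == 10
        assert cv.tp + cv.fn == 10 and cv.tn + cv.fp == 10

    def test_shuffled_labels_perform_at_chance(self, rng):
        fm = separable_features(rng)
        y = rng.permutation(fm.y)
        cv = mvpa.loocv_classify(fm, labels=y)
        # central 95% binomial band around 50% for 20 held-out predictions
        assert 25.0 <= cv.accuracy <= 75.0

    def test_label_flip_swaps_sensitivity_specificity(self, rng):
        x = rng.standard_normal((16, 10))
        x[:8, :3] += 1.0  # imperfectly separable
        y = np.r_[np.ones(8, int), np.zeros(8, int)]
        fm = mvpa.FeatureMatrix(x=x, y=y, voxel_index=np.arange(10))
        fm_flipped = mvpa.FeatureMatrix(x=x, y=1 - y, voxel_index=np.arange(10))
        a = mvpa.loocv_classify(fm)
        b = mvpa.loocv_classify(fm_flipped)
        np.testing.assert_allclose(a.sensitivity, b.specificity, atol=1e-9)
        np.testing.assert_allclose(a.specificity, b.sensitivity, atol=1e-9)
        # relabeling flips the learned hyperplane, so decision values negate
        # and AUC (computed against the flipped labels) is unchanged, while
        # negating scores at *fixed* labels reflects AUC around 0.5
        # up to the libsvm solver tolerance
        np.testing.assert_allclose(b.decision_values, -a.decision_values, atol=5e-3)
        np.testing.assert_allclose(b.auc, a.auc, atol=1e-9)
        np.testing.assert_allclose(mvpa.roc_auc(-a.decision_values, a.true_labels),
                                   1.0 - a.auc, atol=1e-9)

    def test_deterministic_given_features(self, rng):
        fm = separable_features(rng, gap=1.0)
        a = mvpa.loocv_classify(fm)
        b = mvpa.loocv_classify(fm)
        np.testing.assert_array_equal(a.decision_values, b.decision_values)
        assert a.metrics() == b.metrics()

    def test_shuffled_pairing_is_seeded_and_valid(self, rng):
        fm = separable_features(rng, gap=1.0)
        a = mvpa.loocv_classify(fm, pair_rng=42)
        b = mvpa.loocv_classify(fm, pair_rng=42)
        assert a.metrics() == b.metrics()
        assert a.tp + a.fn == 10 and a.tn + a.fp == 10

    def test_single_subject_folds_option(self, rng):
        fm = separable_features(rng)
        cv = mvpa.loocv_classify(fm, pair_folds=False)
        assert cv.n_folds == 20
        assert cv.accuracy == 100.0

    def test_tiny_groups_rejected(self, rng):
        fm = separable_features(rng, n_per_class=2)
        with pytest.raises(InputError):
            mvpa.loocv_classify(fm)


class TestPermutationTest:
    @staticmethod
    def _fake_observed(accuracy):
        dummy = np.zeros(6)
        return mvpa.CrossValResult(predictions=dummy.astype(int),
                                   decision_values=dummy,
                                   true_labels=np.r_[np.ones(3, int), np.zeros(3, int)],
                                   accuracy=accuracy)

    def test_observed_above_every_null_gives_one_over_b_plus_one(self, rng):
        # an observed value no null draw can reach pins the add-one floor
        fm = separable_features(rng, n_per_class=4, n_voxels=5)
        res = mvpa.permutation_test(fm, 99, rng=0, metrics=("accuracy",),
                                    observed=self._fake_observed(100.5))
        assert res["p"]["accuracy"] == pytest.approx(1.0 / 100.0)

    def test_observed_below_every_null_gives_p_one(self, rng):
        fm = separable_features(rng, n_per_class=4, n_voxels=5)
        res = mvpa.permutation_test(fm, 49, rng=0, metrics=("accuracy",),
                                    observed=self._fake_observed(-1.0))
        assert res["p"]["accuracy"] == 1.0

    def test_p_matches_add_one_count_of_returned_null(self, rng):
        fm = separable_features(rng, gap=0.5)
        res = mvpa.permutation_test(fm, 49, rng=3, metrics=("accuracy", "auc"))
        for metric in ("accuracy", "auc"):
            count = np.sum(res["null"][metric] >= res["observed"][metric])
            assert res["p"][metric] == (count + 1) / 50.0

    def test_invalid_b_rejected(self, rng):
        with pytest.raises(InputError):
            mvpa.permutation_test(separable_features(rng), 0)


class TestWeightMap:
    def test_informative_voxel_dominates(self, rng):
        n = 10
        x = np.zeros((2 * n, 2))
        x[:n, 0] = 1.0   # only voxel 0 separates the classes
        x[:, 1] = rng.standard_normal(2 * n) * 0.01
        y = np.r_[np.ones(n, int), np.zeros(n, int)]
        fm = mvpa.FeatureMatrix(x=x, y=y, voxel_index=np.arange(2),
                                grid_shape=(2, 1, 1), affine=np.eye(4))
        wm = mvpa.weight_map(fm, top_fraction=0.5)
        assert abs(wm.weights[0]) > abs(wm.weights[1])
        np.testing.assert_array_equal(wm.top_mask_flat, [0])

    def test_top_fraction_one_covers_mask(self, rng):
        fm = separable_features(rng)
        fm.grid_shape = (30, 1, 1)
        wm = mvpa.weight_map(fm, top_fraction=1.0)
        np.testing.assert_array_equal(np.sort(wm.top_mask_flat), np.arange(30))

    def test_twenty_percent_rule_arithmetic(self, rng):
        fm = separable_features(rng, n_voxels=100)
        fm.grid_shape = (100, 1, 1)
        wm = mvpa.weight_map(fm, top_fraction=0.20)
        assert wm.top_mask_flat.size == 20

    def test_region_summary_percentages_sum_to_100(self, rng):
        fm = separable_features(rng, n_voxels=30)
        fm.grid_shape = (30, 1, 1)
        label_img = np.repeat([1, 2, 3], 10).reshape(30, 1, 1)
        wm = mvpa.weight_map(fm, top_fraction=0.2, label_image=label_img,
                             label_names={1: "A", 2: "B", 3: "C"},
                             region_summary=True)
        assert wm.region_summary["weight_percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_region_summary_needs_label_image(self, rng):
        fm = separable_features(rng)
        fm.grid_shape = (30, 1, 1)
        with pytest.raises(InputError):
            mvpa.weight_map(fm, region_summary=True)


class TestRocAuc:
    def test_perfect_ordering(self):
        assert mvpa.roc_auc([3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
                            [1, 1, 1, 0, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert mvpa.roc_auc([0.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_six_score_toy_matches_pair_counting_oracle(self):
        scores = np.array([0.9, 0.4, 0.4, 0.1, 0.7, -0.2])
        labels = np.array([1, 1, 0, 0, 1, 0])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert mvpa.roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_sklearn_on_random_scores(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        np.testing.assert_allclose(mvpa.roc_auc(scores, labels),
                                   roc_auc_score(labels, scores), atol=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(InputError):
            mvpa.roc_auc([1.0, 2.0], [1, 1])
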