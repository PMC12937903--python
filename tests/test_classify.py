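"""HOG/LBP extraction, subject-level splitting, Random-Forest voting and
confusion-matrix evaluation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mcdm.classify as classify
from mcdm.classify import (
    DatasetSplit, FeatureVector, HOGConfig, LBPConfig, evaluate,
    extract_features, feature_importance, hog_features, lbp_code,
    lbp_histogram, predict, predict_batch, subject_split, train_rf,
)
from mcdm.render import DEFAULT_PALETTE, MCDMImage


def _image(pixels):
    return MCDMImage(pixels=np.asarray(pixels, dtype=np.uint8),
                     palette=DEFAULT_PALETTE)


def _uniform(value, size=64):
    return _image(np.full((size, size, 3), value))


class TestHOG:
    def test_constant_image_gives_zero_descriptor(self):
        assert np.all(hog_features(_uniform(77)) == 0)

    def test_default_descriptor_length_at_256(self):
        img = _uniform(0, size=256)
        # 31 x 31 blocks x 2 x 2 cells x 9 bins
        assert hog_features(img).size == 31 * 31 * 4 * 9 == 34596

    def test_step_edge_concentrates_in_one_orientation_bin(self):
        px = np.zeros((64, 64, 3), np.uint8)
        px[:, 32:, :] = 255  # vertical edge -> horizontal gradient
        v = hog_features(_image(px))
        bins = v.reshape(-1, 9).sum(axis=0)
        assert bins.max() / bins.sum() > 0.9

    def test_oversized_cell_rejected(self):
        with pytest.raises(ValueError, match="larger than image"):
            hog_features(_uniform(0, size=64), HOGConfig(cell=(64, 64)))

    def test_indivisible_image_rejected(self):
        img = _image(np.zeros((65, 64, 3), np.uint8))
        with pytest.raises(ValueError, match="whole cells"):
            hog_features(img)


class TestLBP:
    def test_worked_patch_code_is_85(self):
        # neighbors in sampling order (counterclockwise from rightmost)
        assert lbp_code(5, [6, 2, 7, 3, 8, 1, 9, 4]) == 85

    def test_uniform_image_codes_all_255(self):
        hist = lbp_histogram(_uniform(128))
        assert hist[255] == 1.0

    def test_center_above_neighbors_codes_zero(self):
        px = np.full((5, 5, 3), 50, np.uint8)
        px[2, 2, :] = 200
        hist = lbp_histogram(_image(px))
        assert hist[0] == pytest.approx(1 / 9)  # the spiked center pixel

    def test_histogram_normalized(self, rng):
        img = _image(rng.integers(0, 256, (32, 32, 3)))
        hist = lbp_histogram(img)
        assert hist.size == 256
        assert hist.sum() == pytest.approx(1.0)

    def test_too_small_image_rejected(self):
        img = _image(np.zeros((2, 2, 3), np.uint8))
        with pytest.raises(ValueError, match="too small"):
            lbp_histogram(img)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LBPConfig(p=2)
        with pytest.raises(ValueError):
            LBPConfig(r=0.5)


class TestExtractFeatures:
    def test_layout_and_default_length(self):
        fv = extract_features(_uniform(10, size=256))
        assert len(fv) == fv.hog_length + fv.lbp_length == 34596 + 256

    def test_deterministic(self, rng):
        img = _image(rng.integers(0, 256, (64, 64, 3)))
        a, b = extract_features(img), extract_features(img)
        assert np.array_equal(a.values, b.values)


def _manifest(n_subjects_per_class, images_per_subject=4):
    manifest = []
    for c, label in enumerate(["healthy", "ischemic"]):
        for s in range(n_subjects_per_class):
            sid = f"{'HI'[c]}{s:04d}"
            manifest.extend(
                {"subject_id": sid, "class_label": label}
                for _ in range(images_per_subject)
            )
    return manifest


class TestSubjectSplit:
    def test_1600_images_give_320_test_samples(self):
        split = subject_split(_manifest(200), test_fraction=0.2, seed=0)
        assert len(split.test_indices) == 320
        assert len(split.train_indices) == 1280

    def test_no_subject_overlap_and_stratified(self):
        manifest = _manifest(25)
        split = subject_split(manifest, 0.2, seed=3)
        assert not (split.train_subjects & split.test_subjects)
        test_labels = [manifest[i]["class_label"] for i in split.test_indices]
        assert test_labels.count("healthy") == test_labels.count("ischemic")

    def test_all_images_of_a_subject_stay_together(self):
        manifest = _manifest(10)
        split = subject_split(manifest, 0.2, seed=1)
        for sid in split.test_subjects:
            idx = [i for i, r in enumerate(manifest) if r["subject_id"] == sid]
            assert all(i in set(split.test_indices.tolist()) for i in idx)

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_degenerate_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            subject_split(_manifest(10), fraction, seed=0)

    def test_tiny_class_rejected(self):
        manifest = [{"subject_id": "H1", "class_label": "healthy"},
                    {"subject_id": "I1", "class_label": "ischemic"},
                    {"subject_id": "I2", "class_label": "ischemic"}]
        with pytest.raises(ValueError, match="fewer than 2"):
            subject_split(manifest, 0.5, seed=0)


def _blobs(n_per_class=50, sep=10.0, seed=0, n_features=5):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_class, n_features))
    b = rng.normal(0.0, 1.0, (n_per_class, n_features))
    b[:, 0] += sep
    x = np.vstack([a, b])
    y = ["healthy"] * n_per_class + ["ischemic"] * n_per_class
    return list(x), y


class TestRandomForest:
    @pytest.fixture(scope="class")
    def separable_model(self):
        x, y = _blobs()
        model = train_rf(x, y, grid={"n_estimators": [50], "max_depth": [None]},
                         seed=0)
        return model, x, y

    def test_separable_data_fit_exactly(self, separable_model):
        model, x, y = separable_model
        labels, _ = predict_batch(model, x)
        assert list(labels) == y

    def test_deterministic_given_seed(self):
        x, y = _blobs(sep=2.0)
        probe, _ = _blobs(sep=2.0, seed=99)
        m1 = train_rf(x, y, grid={"n_estimators": [50], "max_depth": [None]}, seed=7)
        m2 = train_rf(x, y, grid={"n_estimators": [50], "max_depth": [None]}, seed=7)
        l1, s1 = predict_batch(m1, probe)
        l2, s2 = predict_batch(m2, probe)
        assert list(l1) == list(l2)
        np.testing.assert_array_equal(s1, s2)

    def test_grid_search_records_best_params(self):
        x, y = _blobs(n_per_class=20)
        model = train_rf(x, y, grid={"n_estimators": [10, 20], "max_depth": [None]},
                         seed=0, cv=3)
        assert model.grid_record["best_params"]["n_estimators"] in (10, 20)
        assert len(model.grid_record["mean_test_scores"]) == 2

    def test_single_class_rejected(self):
        x, _ = _blobs()
        with pytest.raises(ValueError, match="two classes"):
            train_rf(x, ["healthy"] * len(x), seed=0)

    def test_ragged_features_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            train_rf([np.zeros(3), np.zeros(4)], ["a", "b"], seed=0)

    def test_unanimous_vote(self, separable_model):
        model, x, y = separable_model
        label, score = predict(model, x[-1])
        assert label == "ischemic"
        assert score == 1.0

    def test_tie_breaks_to_lexicographically_smaller(self, separable_model, monkeypatch):
        model, x, _ = separable_model
        votes = np.array([["healthy"], ["ischemic"]] * 5, dtype=object).reshape(10, 1)
        monkeypatch.setattr(classify, "_tree_votes", lambda m, xx: votes)
        label, score = predict(model, x[0])
        assert label == "healthy"  # 5/5 tie -> lexicographically smaller
        assert score == 0.5

    def test_dimension_mismatch_rejected(self, separable_model):
        model, _, _ = separable_model
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros(99))


class TestEvaluate:
    def test_reported_confusion_matrix_reproduces_printed_metrics(self):
        """The unique balanced-320 confusion matrix implied by sensitivity
        88.75% and specificity 95.63% yields the published accuracy and F1."""
        truth = ["ischemic"] * 160 + ["healthy"] * 160
        pred = (["ischemic"] * 142 + ["healthy"] * 18
                + ["healthy"] * 153 + ["ischemic"] * 7)
        scores = [1.0] * 142 + [0.0] * 18 + [0.0] * 153 + [1.0] * 7
        report = evaluate(pred, scores, truth)
        assert (report.tp, report.fn, report.tn, report.fp) == (142, 18, 153, 7)
        assert report.accuracy == 92.19
        assert report.sensitivity == 88.75
        assert report.specificity == 95.63
        assert report.f1 == 91.91

    def test_perfect_predictions(self):
        truth = ["ischemic"] * 10 + ["healthy"] * 10
        scores = [1.0] * 10 + [0.0] * 10
        report = evaluate(truth, scores, truth)
        assert (report.accuracy, report.sensitivity,
                report.specificity, report.f1, report.auc) == (100.0,) * 5

    def test_zero_division_flagged(self):
        truth = ["ischemic", "ischemic"]
        pred = ["healthy", "healthy"]
        report = evaluate(pred, [0.0, 0.0], truth)
        assert report.sensitivity == 0.0 and report.f1 == 0.0
        assert "specificity" in report.zero_division_flags  # TN+FP == 0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate([], [], [])

    def test_unknown_positive_class_rejected(self):
        with pytest.raises(ValueError, match="positive_class"):
            evaluate(["a"], [1.0], ["a"], positive_class="b")

    @given(
        tp=st.integers(0, 40), fn=st.integers(0, 40),
        tn=st.integers(0, 40), fp=st.integers(0, 40),
    )
    def test_accuracy_identity_over_confusion_matrices(self, tp, fn, tn, fp):
        """accuracy = (sens * P + spec * N) / (P + N) on the raw rates."""
        if tp + fn == 0 or tn + fp == 0:
            return
        truth = ["ischemic"] * (tp + fn) + ["healthy"] * (tn + fp)
        pred = (["ischemic"] * tp + ["healthy"] * fn
                + ["healthy"] * tn + ["ischemic"] * fp)
        scores = [1.0 if p == "ischemic" else 0.0 for p in pred]
        r = evaluate(pred, scores, truth)
        p_count, n_count = tp + fn, tn + fp
        expected = (r.sensitivity * p_count + r.specificity * n_count) / (p_count + n_count)
        assert r.accuracy == pytest.approx(expected, abs=0.02)

    def test_auc_of_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(20):
            truth = ["ischemic"] * 100 + ["healthy"] * 100
            scores = rng.uniform(0, 1, 200)
            pred = ["ischemic" if s >= 0.5 else "healthy" for s in scores]
            aucs.append(evaluate(pred, scores, truth).auc)
        assert np.mean(aucs) == pytest.approx(50.0, abs=5.0)

    def test_auc_of_separated_scores_is_100(self):
        truth = ["ischemic"] * 5 + ["healthy"] * 5
        scores = [0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.3, 0.15, 0.05]
        pred = ["ischemic"] * 5 + ["healthy"] * 5
        assert evaluate(pred, scores, truth).auc == 100.0


class TestFeatureImportance:
    def test_normalized_and_informative_feature_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (200, 6))
        y = np.where(x[:, 3] > 0, "ischemic", "healthy")
        model = train_rf(list(x), list(y),
                         grid={"n_estimators": [50], "max_depth": [None]}, seed=0)
        ranked = feature_importance(model, layout=(4, 2))
        assert ranked[0][0] == 3
        total = sum(v for _, _, v in ranked)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for _, _, v in ranked)
        assert {d for _, d, _ in ranked} == {"HOG", "LBP"}

    def test_untrained_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier
        from mcdm.classify import ForestModel
        model = ForestModel(estimator=RandomForestClassifier(), n_trees=10,
                            seed=0, grid_record={}, classes=("a", "b"))
        with pytest.raises(ValueError, match="not trained"):
            feature_importance(model, layout=(1, 1))

    def test_layout_mismatch_rejected(self):
        x, y = _blobs(n_per_class=20)
        model = train_rf(x, y, grid={"n_estimators": [10], "max_depth": [None]}, seed=0)
        with pytest.raises(ValueError, match="layout"):
            feature_importance(model, layout=(1, 1))
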