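"""Reference patch classifier, evaluation metrics and saliency."""

import numpy as np
import pandas as pd
import pytest

from gastroslide.patch_model import (
    CapabilityError,
    ProbabilityTriple,
    ReferenceClassifier,
    evaluate,
    metrics_from_confusion,
    saliency_map,
    train_reference_classifier,
)
from gastroslide.patching import Patch
from gastroslide.synthdata import generate_patch_set


class TestProbabilityTriple:
    def test_valid_triple_and_malignancy(self):
        t = ProbabilityTriple(0.2, 0.3, 0.5)
        assert t.malignancy == pytest.approx(0.8)

    @pytest.mark.parametrize(
        "triple", [(0.5, 0.5, 0.5), (-0.1, 0.6, 0.5), (0.2, 0.2, 0.2)]
    )
    def test_invalid_triples_rejected(self, triple):
        with pytest.raises(ValueError):
            ProbabilityTriple(*triple)


class TestTraining:
    def test_holdout_accuracy_on_synthetic_textures(
        self, trained_classifier, eval_patch_set
    ):
        report = evaluate(trained_classifier, eval_patch_set)
        assert report.accuracy >= 0.85

    def test_prediction_sums_to_one(self, trained_classifier, eval_patch_set):
        triple = trained_classifier.predict(eval_patch_set[0])
        assert triple.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_training_is_deterministic(self, patch_set, eval_patch_set):
        rasters = np.stack([p.raster for p in eval_patch_set])
        a = train_reference_classifier(patch_set, seed=5)
        b = train_reference_classifier(patch_set, seed=5)
        assert np.array_equal(
            a.predict_proba_batch(rasters), b.predict_proba_batch(rasters)
        )

    def test_single_class_input_rejected(self, patch_set):
        only_normal = [p for p in patch_set if p.label == "normal"]
        with pytest.raises(ValueError, match="2 classes"):
            train_reference_classifier(only_normal)

    def test_permuted_labels_give_chance_accuracy(self, patch_set):
        """Random label permutation leaves nothing to learn: held-out
        accuracy stays in the 3-class chance band."""
        rng = np.random.default_rng(17)
        labels = [p.label for p in patch_set]
        shuffled = list(rng.permutation(labels))
        permuted = [
            Patch(raster=p.raster, x=p.x, y=p.y, scale=p.scale, label=l)
            for p, l in zip(patch_set, shuffled)
        ]
        model = train_reference_classifier(permuted, seed=1)
        fresh = generate_patch_set(100, patch_size=96, seed=909)
        report = evaluate(model, fresh)
        assert 0.25 <= report.accuracy <= 0.42

    def test_save_load_roundtrip(self, trained_classifier, eval_patch_set, tmp_path):
        path = tmp_path / "model.npz"
        trained_classifier.save(path)
        loaded = ReferenceClassifier.load(path)
        rasters = np.stack([p.raster for p in eval_patch_set[:6]])
        assert np.array_equal(
            trained_classifier.predict_proba_batch(rasters),
            loaded.predict_proba_batch(rasters),
        )
        assert loaded.metadata == trained_classifier.metadata


class TestEvaluate:
    def test_perfect_predictions(self, patch_set, trained_classifier):
        report = evaluate(trained_classifier, patch_set)  # training set
        assert report.confusion.to_numpy().sum() == len(patch_set)

    def test_metrics_match_hand_arithmetic(self):
        cm = pd.DataFrame(
            [[50, 5, 5], [10, 30, 0], [0, 2, 48]],
            index=("normal", "gastritis", "cancer"),
            columns=("normal", "gastritis", "cancer"),
        )
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(128 / 150)
        assert m["sensitivity"]["gastritis"] == pytest.approx(30 / 40)
        # specificity of cancer: TN = 150 - 50(row) - 53(col) + 48
        assert m["specificity"]["cancer"] == pytest.approx((150 - 50 - 53 + 48) / 100)

    def test_all_cancer_predictor_sensitivity_specificity(self):
        class AllCancer(ReferenceClassifier):
            def __init__(self):
                self.metadata = {}

            def predict_proba_batch(self, rasters):
                out = np.zeros((len(rasters), 3))
                out[:, 2] = 1.0
                return out

        patches = generate_patch_set(5, patch_size=32, seed=3)
        report = evaluate(AllCancer(), patches)
        assert report.sensitivity["cancer"] == pytest.approx(1.0)
        assert report.specificity["cancer"] == pytest.approx(0.0)

    def test_absent_class_metric_is_nan_not_zero(self, trained_classifier):
        patches = generate_patch_set(
            4, patch_size=96, seed=5, classes=("normal", "cancer")
        )
        report = evaluate(trained_classifier, patches)
        assert np.isnan(report.sensitivity["gastritis"])


class TestSaliency:
    def test_constant_classifier_gives_all_zero_map(self, patch_set):
        n_feats = 16 * 16 * 3
        model = ReferenceClassifier(
            weights=np.zeros((3, n_feats)),
            bias=np.zeros(3),
            feature_mean=np.zeros(n_feats),
            feature_scale=np.ones(n_feats),
            trained_classes=("normal", "gastritis", "cancer"),
            pool_side=16,
        )
        sal = saliency_map(model, patch_set[0], "cancer")
        assert not sal.any()

    def test_linear_weights_map_through_to_pixels(self):
        """With pool grid == pixel grid, the saliency map equals the
        channel-max |weight| matrix rescaled to [0, 1]."""
        rng = np.random.default_rng(9)
        side = 8
        w = rng.normal(size=(3, side * side * 3))
        model = ReferenceClassifier(
            weights=w,
            bias=np.zeros(3),
            feature_mean=np.zeros(side * side * 3),
            feature_scale=np.ones(side * side * 3),
            trained_classes=("normal", "gastritis", "cancer"),
            pool_side=side,
        )
        raster = rng.integers(0, 256, (side, side, 3)).astype(np.uint8)
        sal = saliency_map(model, raster, "cancer")
        expected = np.abs(w[2].reshape(side, side, 3)).max(axis=2)
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        assert np.allclose(sal, expected)

    def test_finite_difference_matches_analytic_gradient(
        self, trained_classifier, eval_patch_set
    ):
        """Central finite differences at step 1 on a random pixel subset
        correlate >= 0.95 with the analytic class-score gradient."""
        raster = eval_patch_set[0].raster.astype(np.float64)
        grad = trained_classifier.class_score_gradient(
            eval_patch_set[0].raster, "cancer"
        )
        j = trained_classifier.trained_classes.index("cancer")

        def score(arr):
            feats = arr[None]
            return trained_classifier._logits(feats)[0, j]

        rng = np.random.default_rng(10)
        analytic, numeric = [], []
        for _ in range(200):
            y, x, c = (
                rng.integers(0, raster.shape[0]),
                rng.integers(0, raster.shape[1]),
                rng.integers(0, 3),
            )
            up = raster.copy()
            up[y, x, c] += 1
            down = raster.copy()
            down[y, x, c] -= 1
            numeric.append((score(up) - score(down)) / 2.0)
            analytic.append(grad[y, x, c])
        r = np.corrcoef(analytic, numeric)[0, 1]
        assert r >= 0.95

    def test_gradient_unavailable_raises_capability_error(self, patch_set):
        from gastroslide.patch_model import PatchClassifier

        with pytest.raises(CapabilityError):
            PatchClassifier().class_score_gradient(patch_set[0].raster, "cancer")
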