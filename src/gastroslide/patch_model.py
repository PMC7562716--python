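"""Patch classification: probability contract, reference model, saliency.

The heatmap, slide-classification and survival stages depend only on a
probabilistic patch-classifier *contract*: a mapping from an RGB patch to
a (normal, gastritis, cancer) probability triple whose malignancy reading
is ``1 - p_normal``.  Any model honouring the contract can be plugged in.

The bundled reference classifier is deliberately small: block-mean pooling
of the raw patch to a coarse grid, feature standardization, and a
multinomial logistic regression trained with the cross-entropy objective.
It is linear in the pooled pixels, so class-score gradients (and hence
saliency maps) are analytic, and it is strong enough to separate the
procedural lesion textures.  It does not claim the representational power
of a deep network; it exists so the pipeline around the contract is fully
testable at desk scale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve, auc as sk_auc

from .patching import Patch
from .slide_io import LESION_CLASSES


class CapabilityError(RuntimeError):
    """The classifier does not support the requested operation."""


@dataclasses.dataclass(frozen=True)
class ProbabilityTriple:
    """Class probabilities of one patch; sums to 1 within 1e-6."""

    p_normal: float
    p_gastritis: float
    p_cancer: float

    def __post_init__(self) -> None:
        vals = (self.p_normal, self.p_gastritis, self.p_cancer)
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability {v} outside [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {sum(vals)}, expected 1")

    @property
    def malignancy(self) -> float:
        """Probability of not being normal mucosa."""
        return 1.0 - self.p_normal

    def as_array(self) -> np.ndarray:
        return np.array([self.p_normal, self.p_gastritis, self.p_cancer])


class PatchClassifier:
    """Contract every patch classifier must honour.

    ``classes`` is the fixed (normal, gastritis, cancer) order; predictions
    must be deterministic for a fixed trained state.
    """

    classes = LESION_CLASSES
    metadata: dict

    def predict_proba_batch(self, rasters: np.ndarray) -> np.ndarray:
        """(n, h, w, 3) uint8 rasters -> (n, 3) probabilities."""
        raise NotImplementedError

    def predict(self, patch: Patch | np.ndarray) -> ProbabilityTriple:
        raster = patch.raster if isinstance(patch, Patch) else np.asarray(patch)
        probs = self.predict_proba_batch(raster[None])[0]
        probs = probs / probs.sum()
        return ProbabilityTriple(*[float(p) for p in probs])

    def class_score_gradient(
        self, raster: np.ndarray, class_name: str
    ) -> np.ndarray:
        raise CapabilityError(
            f"{type(self).__name__} exposes no class-score gradient"
        )


def _pool_edges(side: int, pool_side: int) -> np.ndarray:
    return np.linspace(0, side, pool_side + 1).round().astype(int)


def _pool(rasters: np.ndarray, pool_side: int) -> np.ndarray:
    """Block-mean pool (n, h, w, 3) rasters to (n, pool_side**2 * 3)."""
    n, h, w, _ = rasters.shape
    ye = _pool_edges(h, pool_side)
    xe = _pool_edges(w, pool_side)
    arr = rasters.astype(np.float64)
    rows = np.add.reduceat(arr, ye[:-1], axis=1)
    cells = np.add.reduceat(rows, xe[:-1], axis=2)
    counts = np.outer(np.diff(ye), np.diff(xe))[None, :, :, None]
    return (cells / counts).reshape(n, -1)


@dataclasses.dataclass
class ClassifierConfig:
    """Reference-classifier hyperparameters.

    ``pool_side`` is the coarse pooling grid; ``c`` the inverse L2
    regularization strength of the logistic regression; ``max_iter`` the
    LBFGS iteration cap.
    """

    pool_side: int = 16
    c: float = 1.0
    max_iter: int = 500


class ReferenceClassifier(PatchClassifier):
    """Pooled-pixel multinomial logistic regression.

    Owns its parameters as plain arrays (weights, bias, feature mean and
    scale), so prediction is pure numpy, saving/loading is a single
    ``.npz`` archive with embedded JSON metadata, and the class-score
    gradient with respect to input pixels is analytic.
    """

    def __init__(
        self,
        weights: np.ndarray,  # (n_classes_trained, n_features) logit weights
        bias: np.ndarray,
        feature_mean: np.ndarray,
        feature_scale: np.ndarray,
        trained_classes: tuple[str, ...],
        pool_side: int,
        metadata: dict | None = None,
    ):
        self.weights = np.asarray(weights, dtype=np.float64)
        self.bias = np.asarray(bias, dtype=np.float64)
        self.feature_mean = np.asarray(feature_mean, dtype=np.float64)
        self.feature_scale = np.asarray(feature_scale, dtype=np.float64)
        self.trained_classes = tuple(trained_classes)
        self.pool_side = int(pool_side)
        self.metadata = metadata or {}

    # -- inference --------------------------------------------------------

    def _logits(self, rasters: np.ndarray) -> np.ndarray:
        feats = _pool(rasters, self.pool_side)
        z = (feats - self.feature_mean) / self.feature_scale
        return z @ self.weights.T + self.bias

    def predict_proba_batch(self, rasters: np.ndarray) -> np.ndarray:
        rasters = np.asarray(rasters)
        if rasters.ndim != 4:
            raise ValueError("expected a batch of rasters (n, h, w, 3)")
        logits = self._logits(rasters)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        out = np.zeros((rasters.shape[0], 3))
        for j, cls in enumerate(self.trained_classes):
            out[:, LESION_CLASSES.index(cls)] = p[:, j]
        return out

    def class_score_gradient(self, raster: np.ndarray, class_name: str) -> np.ndarray:
        """d(unnormalized class score)/d(pixel), shape (h, w, 3).

        The score is the class logit; as the model is linear in the pooled
        pixels the gradient is the standardized weight of each pooled cell
        spread uniformly over the pixels it pools.
        """
        if class_name not in self.trained_classes:
            raise CapabilityError(
                f"class {class_name!r} was not in the training classes "
                f"{self.trained_classes}"
            )
        raster = np.asarray(raster)
        h, w, _ = raster.shape
        j = self.trained_classes.index(class_name)
        wvec = (self.weights[j] / self.feature_scale).reshape(
            self.pool_side, self.pool_side, 3
        )
        ye = _pool_edges(h, self.pool_side)
        xe = _pool_edges(w, self.pool_side)
        grad = np.zeros((h, w, 3))
        for by in range(self.pool_side):
            for bx in range(self.pool_side):
                area = (ye[by + 1] - ye[by]) * (xe[bx + 1] - xe[bx])
                grad[ye[by] : ye[by + 1], xe[bx] : xe[bx + 1], :] = (
                    wvec[by, bx] / max(area, 1)
                )
        return grad

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            weights=self.weights,
            bias=self.bias,
            feature_mean=self.feature_mean,
            feature_scale=self.feature_scale,
            trained_classes=np.array(self.trained_classes),
            pool_side=np.array(self.pool_side),
            metadata=np.array(json.dumps(self.metadata)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceClassifier":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                weights=z["weights"],
                bias=z["bias"],
                feature_mean=z["feature_mean"],
                feature_scale=z["feature_scale"],
                trained_classes=tuple(str(c) for c in z["trained_classes"]),
                pool_side=int(z["pool_side"]),
                metadata=json.loads(str(z["metadata"])),
            )


def train_reference_classifier(
    patches: list[Patch],
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> ReferenceClassifier:
    """Train the reference classifier on labeled patches.

    Requires at least two classes.  Deterministic under ``seed`` (LBFGS
    itself is deterministic; the seed is recorded and used for any future
    stochastic solver).
    """
    config = config or ClassifierConfig()
    labeled = [p for p in patches if p.label is not None]
    labels = [p.label for p in labeled]
    present = sorted(set(labels), key=LESION_CLASSES.index)
    if len(present) < 2:
        raise ValueError(
            f"training needs >= 2 classes, got {len(present)}: {present}"
        )
    rasters = np.stack([p.raster for p in labeled])
    feats = _pool(rasters, config.pool_side)
    mean = feats.mean(axis=0)
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    z = (feats - mean) / scale
    y = np.array([present.index(l) for l in labels])
    model = LogisticRegression(
        C=config.c, max_iter=config.max_iter, solver="lbfgs", random_state=seed
    )
    model.fit(z, y)
    if len(present) == 2:
        weights = np.vstack([np.zeros_like(model.coef_[0]), model.coef_[0]])
        bias = np.array([0.0, float(model.intercept_[0])])
    else:
        weights = model.coef_
        bias = model.intercept_
    return ReferenceClassifier(
        weights=weights,
        bias=bias,
        feature_mean=mean,
        feature_scale=scale,
        trained_classes=tuple(present),
        pool_side=config.pool_side,
        metadata={
            "name": "reference-pooled-logistic",
            "seed": seed,
            "pool_side": config.pool_side,
            "c": config.c,
            "n_training_patches": len(labeled),
            "classes": present,
        },
    )


class NormalizingClassifier(PatchClassifier):
    """Wrap a classifier so every raster is stain-normalized to a
    reference profile before prediction.  Patches whose stain cannot be
    estimated pass through un-normalized (the wrapped model still sees
    them)."""

    def __init__(self, base: PatchClassifier, reference, beta=0.15, alpha=0.01):
        from .stain import normalize_to_reference

        self._base = base
        self._reference = reference
        self._beta = beta
        self._alpha = alpha
        self._normalize = normalize_to_reference
        self.metadata = {**getattr(base, "metadata", {}), "stain_normalized": True}

    def predict_proba_batch(self, rasters: np.ndarray) -> np.ndarray:
        normed = np.stack(
            [
                self._normalize(
                    r, self._reference, beta=self._beta, alpha=self._alpha
                ).image
                for r in rasters
            ]
        )
        return self._base.predict_proba_batch(normed)


# -- evaluation ------------------------------------------------------------


@dataclasses.dataclass
class EvaluationReport:
    """Classifier metrics on a labeled patch set.

    ``sensitivity``/``specificity`` are per class (one-vs-rest recall and
    true-negative rate); a metric whose class is absent from the
    evaluation set is NaN (undefined), never 0.  ``roc`` is the
    (fpr, tpr, thresholds) sweep of the malignancy probability for the
    binary benign-versus-cancer reading (normal + gastritis merged as
    benign), with its AUC; both are None when either side is absent.
    """

    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    confusion: pd.DataFrame
    roc: tuple[np.ndarray, np.ndarray, np.ndarray] | None
    roc_auc: float | None


def metrics_from_confusion(confusion: pd.DataFrame) -> dict:
    """Accuracy and per-class sensitivity/specificity from a confusion
    matrix (rows: true class, columns: predicted class)."""
    cm = confusion.to_numpy(dtype=float)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    sensitivity = {}
    specificity = {}
    for i, cls in enumerate(confusion.index):
        pos = cm[i].sum()
        neg = total - pos
        sensitivity[cls] = float(cm[i, i] / pos) if pos else float("nan")
        tn = total - pos - cm[:, i].sum() + cm[i, i]
        specificity[cls] = float(tn / neg) if neg else float("nan")
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


def evaluate(
    classifier: PatchClassifier,
    patches: list[Patch],
) -> EvaluationReport:
    """Evaluate a classifier on labeled patches."""
    labeled = [p for p in patches if p.label is not None]
    if not labeled:
        raise ValueError("evaluation set is empty")
    rasters = np.stack([p.raster for p in labeled])
    probs = classifier.predict_proba_batch(rasters)
    truth = np.array([LESION_CLASSES.index(p.label) for p in labeled])
    pred = probs.argmax(axis=1)
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(truth, pred):
        cm[t, p] += 1
    confusion = pd.DataFrame(cm, index=LESION_CLASSES, columns=LESION_CLASSES)
    metrics = metrics_from_confusion(confusion)
    # metrics for absent classes stay undefined (NaN)
    for i, cls in enumerate(LESION_CLASSES):
        if (truth == i).sum() == 0:
            metrics["sensitivity"][cls] = float("nan")
    is_cancer = truth == LESION_CLASSES.index("cancer")
    roc = roc_auc = None
    if is_cancer.any() and (~is_cancer).any():
        malignancy = 1.0 - probs[:, LESION_CLASSES.index("normal")]
        fpr, tpr, thr = roc_curve(is_cancer, malignancy)
        roc = (fpr, tpr, thr)
        roc_auc = float(sk_auc(fpr, tpr))
    return EvaluationReport(
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        confusion=confusion,
        roc=roc,
        roc_auc=roc_auc,
    )


def saliency_map(
    classifier: PatchClassifier,
    patch: Patch | np.ndarray,
    class_name: str,
) -> np.ndarray:
    """Gradient saliency: per-pixel channel-max |d score / d pixel|,
    min-max rescaled to [0, 1] (an all-zero gradient stays all-zero)."""
    raster = patch.raster if isinstance(patch, Patch) else np.asarray(patch)
    grad = classifier.class_score_gradient(raster, class_name)
    sal = np.abs(grad).max(axis=2)
    lo, hi = sal.min(), sal.max()
    if hi > lo:
        sal = (sal - lo) / (hi - lo)
    return sal
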