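"""Heatmap morphometry (44 features) and slide-level classification.

From each slide's malignancy heatmap a fixed vector of 44 features is
extracted and fed to a random-forest classifier.  The features summarize
the geometry of thresholded tumor regions (counts, areas, perimeters,
eccentricities, extents and their moments), the distribution of per-cell
malignancy probabilities, and the proportions of cells in high-probability
bins.

Conventions (the region statistics are otherwise underdetermined):

* a cell is a *tumor cell* at threshold ``t`` iff its probability is >= t;
* regions are 8-connected components of tumor cells over tissue;
* area is the cell count, perimeter the count of exposed 4-neighbor cell
  edges, eccentricity and major-axis length come from the ellipse with the
  same second central moments as the region (point-mass pixels), extent is
  area over bounding-box area;
* moments are population (uncorrected) statistics, kurtosis is Pearson
  (non-excess); every statistic of an empty region set is 0;
* the mode of the continuous probabilities is the mean of the
  probabilities falling in the fullest of 100 equal bins on [0, 1] (ties
  to the lowest bin), so a constant field has its own value as mode;
* areas and lengths are in heatmap cells (the cell size is metadata).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from sklearn.ensemble import RandomForestClassifier

from .heatmap import Heatmap

_MOMENT_NAMES = ("max", "mean", "var", "skew", "kurt")

#: Stable names of the 44 features, in order (1-based indices 1..44).
FEATURE_NAMES: tuple[str, ...] = (
    ("n_regions_area_ge_5pct_p90", "tumor_area_fraction_p90",
     "largest_region_area_p50", "largest_region_major_axis_p50",
     "fraction_cells_p90", "mean_prob_tumor_cells_p90")
    + tuple(f"region_area_{m}_p90" for m in _MOMENT_NAMES)
    + tuple(f"region_perimeter_{m}_p90" for m in _MOMENT_NAMES)
    + tuple(f"region_eccentricity_{m}_p90" for m in _MOMENT_NAMES)
    + tuple(f"region_extent_{m}_p50" for m in _MOMENT_NAMES)
    + ("prob_mean", "prob_var", "prob_std", "prob_median", "prob_mode",
       "prob_min", "prob_max", "prob_range", "prob_sum",
       "mean_malignant_probability")
    + ("frac_prob_gt_0.999", "frac_prob_0.99_0.999", "frac_prob_0.95_0.99",
       "frac_prob_0.9_0.95", "frac_prob_0.8_0.9", "frac_prob_0.7_0.8",
       "frac_prob_0.6_0.7", "frac_prob_0.5_0.6")
)

#: The probability bins of features 37-44: strict `> 0.999` for the first,
#: half-open (low, high] for the rest.
PROBABILITY_BINS: tuple[tuple[float, float], ...] = (
    (0.999, np.inf), (0.99, 0.999), (0.95, 0.99), (0.9, 0.95),
    (0.8, 0.9), (0.7, 0.8), (0.6, 0.7), (0.5, 0.6),
)

#: 1-based indices of features that live on an unbounded positive scale
#: (counts, areas, lengths, sums); the rest lie in the unit interval.
POSITIVE_FEATURE_INDICES = frozenset(
    {1, 3, 4} | set(range(7, 17)) | {35}
)

assert len(FEATURE_NAMES) == 44


@dataclasses.dataclass
class FeatureVector44:
    """The 44 heatmap features with stable names and order."""

    values: np.ndarray
    slide_id: str = ""

    names = FEATURE_NAMES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (44,):
            raise ValueError(f"expected 44 features, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("features must be finite")
        self.values = v

    def __len__(self) -> int:
        return 44

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.slide_id)


@dataclasses.dataclass
class TumorRegion:
    """One connected tumor region of a thresholded heatmap."""

    area: int
    perimeter: int
    eccentricity: float
    extent: float
    major_axis_length: float
    mean_probability: float


@dataclasses.dataclass
class TumorRegionSet:
    regions: list[TumorRegion]
    threshold: float

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def _region_shape_props(ys: np.ndarray, xs: np.ndarray) -> tuple[float, float]:
    """(eccentricity, major_axis_length) of a pixel set via the
    equivalent-ellipse second central moments."""
    n = ys.size
    cy, cx = ys.mean(), xs.mean()
    mu20 = float(((xs - cx) ** 2).mean())
    mu02 = float(((ys - cy) ** 2).mean())
    mu11 = float(((xs - cx) * (ys - cy)).mean())
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    l1 = (mu20 + mu02 + common) / 2.0
    l2 = (mu20 + mu02 - common) / 2.0
    if l1 <= 0:
        return 0.0, 0.0
    ecc = float(np.sqrt(max(0.0, 1.0 - l2 / l1)))
    return ecc, float(4.0 * np.sqrt(l1))


def _region_perimeter(component: np.ndarray) -> int:
    """Count of cell edges between the region and its complement."""
    padded = np.pad(component, 1)
    horiz = np.count_nonzero(padded[:, 1:] != padded[:, :-1])
    vert = np.count_nonzero(padded[1:, :] != padded[:-1, :])
    return int(horiz + vert)


def threshold_regions(hm: Heatmap, p_threshold: float) -> TumorRegionSet:
    """8-connected tumor regions at a probability threshold (>= rule)."""
    cells = hm.tissue_cells()
    with np.errstate(invalid="ignore"):
        binary = (hm.values >= p_threshold) & cells
    labels = cc_label(binary, connectivity=2)
    regions = []
    for lbl in range(1, labels.max() + 1):
        component = labels == lbl
        ys, xs = np.nonzero(component)
        area = int(ys.size)
        h = int(ys.max() - ys.min() + 1)
        w = int(xs.max() - xs.min() + 1)
        ecc, major = _region_shape_props(ys.astype(float), xs.astype(float))
        regions.append(
            TumorRegion(
                area=area,
                perimeter=_region_perimeter(component),
                eccentricity=ecc,
                extent=float(area / (h * w)),
                major_axis_length=major,
                mean_probability=float(hm.values[component].mean()),
            )
        )
    return TumorRegionSet(regions=regions, threshold=p_threshold)


def _moments(vals: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(max, mean, population variance, skewness, Pearson kurtosis) with
    the empty-set and zero-variance conventions."""
    arr = np.asarray(list(vals), dtype=np.float64)
    if arr.size == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    mean = float(arr.mean())
    var = float(((arr - mean) ** 2).mean())
    if var <= 0:
        return (float(arr.max()), mean, 0.0, 0.0, 0.0)
    m3 = float(((arr - mean) ** 3).mean())
    m4 = float(((arr - mean) ** 4).mean())
    return (
        float(arr.max()),
        mean,
        var,
        m3 / var**1.5,
        m4 / var**2,
    )


def extract_feature_vector(hm: Heatmap) -> FeatureVector44:
    """The 44-feature morphometry of one heatmap.

    Statistics of per-cell probabilities (features 27-36) run over *all*
    covered tissue cells; region features use the thresholds named in
    :data:`FEATURE_NAMES` (p90 = 0.90, p50 = 0.50).
    """
    cells = hm.tissue_cells()
    n_tissue = int(cells.sum())
    if n_tissue == 0:
        raise ValueError("heatmap has no tissue cells")
    probs = hm.values[cells]

    regions90 = threshold_regions(hm, 0.90)
    regions50 = threshold_regions(hm, 0.50)

    out = np.zeros(44)
    out[0] = sum(1 for r in regions90 if r.area >= 0.05 * n_tissue)
    tumor90 = probs >= 0.90
    out[1] = tumor90.mean()
    if len(regions50):
        largest = max(regions50, key=lambda r: r.area)
        out[2] = largest.area
        out[3] = largest.major_axis_length
    out[4] = tumor90.mean()
    out[5] = float(probs[tumor90].mean()) if tumor90.any() else 0.0
    out[6:11] = _moments([r.area for r in regions90])
    out[11:16] = _moments([r.perimeter for r in regions90])
    out[16:21] = _moments([r.eccentricity for r in regions90])
    out[21:26] = _moments([r.extent for r in regions50])

    mean = float(probs.mean())
    var = float(((probs - mean) ** 2).mean())
    bin_idx = np.minimum((probs * 100).astype(np.int64), 99)
    fullest = int(np.argmax(np.bincount(bin_idx, minlength=100)))
    mode = float(probs[bin_idx == fullest].mean())
    out[26] = mean
    out[27] = var
    out[28] = np.sqrt(var)
    out[29] = float(np.median(probs))
    out[30] = mode
    out[31] = float(probs.min())
    out[32] = float(probs.max())
    out[33] = float(probs.max() - probs.min())
    out[34] = float(probs.sum())
    out[35] = mean

    for k, (lo, hi) in enumerate(PROBABILITY_BINS):
        out[36 + k] = float(((probs > lo) & (probs <= hi)).mean())
    return FeatureVector44(values=out, slide_id=hm.slide_id)


# -- slide-level random forest ---------------------------------------------


@dataclasses.dataclass
class ForestConfig:
    """Random-forest hyperparameters (500 trees, sqrt-features splits)."""

    n_estimators: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    oob_score: bool = True


@dataclasses.dataclass
class SlideClassifierModel:
    """A trained slide-level random forest over the 44 features."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    oob_accuracy: float | None = None


def train_slide_classifier(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    config: ForestConfig | None = None,
    seed: int = 0,
) -> SlideClassifierModel:
    """Train the slide-level random forest on 44-feature rows.

    Deterministic under ``seed``; the out-of-bag accuracy is exposed on
    the returned model.
    """
    config = config or ForestConfig()
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = FEATURE_NAMES
    if X.ndim != 2 or X.shape[1] != 44:
        raise ValueError(f"expected (n, 44) features, got {X.shape}")
    y = np.asarray(labels)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 slides to train")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 slide classes")
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        max_depth=config.max_depth,
        oob_score=config.oob_score,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return SlideClassifierModel(
        forest=forest,
        feature_names=names,
        classes=tuple(forest.classes_),
        oob_accuracy=float(forest.oob_score_) if config.oob_score else None,
    )


def classify_slide(
    model: SlideClassifierModel, features: FeatureVector44 | np.ndarray
) -> tuple[str, dict[str, float]]:
    """Majority-vote label and per-class vote fractions for one slide."""
    vec = features.values if isinstance(features, FeatureVector44) else np.asarray(
        features, dtype=float
    )
    if vec.shape != (44,):
        raise ValueError(f"expected a 44-feature vector, got shape {vec.shape}")
    probs = model.forest.predict_proba(vec[None])[0]
    label = model.classes[int(np.argmax(probs))]
    return label, {c: float(p) for c, p in zip(model.classes, probs)}


def split_cohort(
    ids: Sequence,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Shuffle ids into (train, test, validation) lists.

    Sizes are ``round(n * f_train)`` and ``round(n * f_val)`` with the
    remainder going to the test set, so the three lists partition the
    input.  Deterministic under ``seed``.
    """
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 ids to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    f_train, _f_test, f_val = fractions
    n_train = int(round(n * f_train))
    n_val = int(round(n * f_val))
    n_test = n - n_train - n_val
    if min(n_train, n_test, n_val) < 0:
        raise ValueError("fractions produce a negative split")
    order = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train : n_train + n_test]]
    val = [ids[i] for i in order[n_train + n_test :]]
    return train, test, val
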