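"""Survival analysis: discretized outcome forests, Kaplan-Meier, log-rank.

Follow-up of cancer patients is right-censored, so the survival outcome is
handled two ways:

* a three-class discretization (died < 1 year; died within 5 years but
  survived >= 1 year; survived >= 5 years) feeding random-forest
  classifiers on clinical covariates, heatmap features, or both.  Records
  censored before 60 months cannot be assigned a class and are excluded
  from the forests;
* Kaplan-Meier product-limit curves with Greenwood-variance confidence
  bands and two-group log-rank tests, which handle censoring natively.
  Groups are formed by splitting a feature at its sample median, ties
  going to the upper (>= median) group.

Feature importance of a trained forest is the number of internal tree
splits determined by each feature, normalized to sum to 1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .synthdata import CLINICAL_COLUMNS
from .wsi_features import FEATURE_NAMES, ForestConfig

#: The three discretized survival classes, in order of worsening outcome
#: reversed (class 1 = worst).
SURVIVAL_CLASSES = ("died_lt_1y", "died_1_5y", "survived_ge_5y")


def discretize_survival(duration_months: float, event: int) -> str | None:
    """Three-class discretization of a right-censored record.

    Died before 12 months -> class 1; died in [12, 60) -> class 2;
    followed (dead or alive) to >= 60 months -> class 3; alive with less
    than 60 months of follow-up -> ``None`` (class indeterminable under
    censoring).
    """
    if duration_months <= 0:
        raise ValueError("duration must be positive")
    if duration_months >= 60.0:
        return SURVIVAL_CLASSES[2]
    if event:
        return SURVIVAL_CLASSES[0] if duration_months < 12.0 else SURVIVAL_CLASSES[1]
    return None


def discretize_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Add a ``survival_class`` column and drop indeterminable records."""
    classes = [
        discretize_survival(d, e)
        for d, e in zip(frame["duration_months"], frame["event"])
    ]
    out = frame.copy()
    out["survival_class"] = classes
    return out[out["survival_class"].notna()].reset_index(drop=True)


FEATURE_SETS = ("clinical", "ai", "all")


def _feature_columns(feature_set: str) -> tuple[list[str], list[str]]:
    """(column names, category tags) of a feature block."""
    if feature_set == "clinical":
        return list(CLINICAL_COLUMNS), ["clinical"] * len(CLINICAL_COLUMNS)
    if feature_set == "ai":
        return list(FEATURE_NAMES), ["AI"] * len(FEATURE_NAMES)
    if feature_set == "all":
        cols = list(CLINICAL_COLUMNS) + list(FEATURE_NAMES)
        cats = ["clinical"] * len(CLINICAL_COLUMNS) + ["AI"] * len(FEATURE_NAMES)
        return cols, cats
    raise ValueError(f"feature_set must be one of {FEATURE_SETS}")


@dataclasses.dataclass
class SurvivalFitResult:
    """A fitted survival forest with its held-out evaluation."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    categories: tuple[str, ...]
    classes: tuple[str, ...]
    accuracy: float
    confusion: pd.DataFrame
    n_train: int
    n_test: int


def fit_survival_rf(
    frame: pd.DataFrame,
    feature_set: str = "all",
    split: float = 0.75,
    config: ForestConfig | None = None,
    seed: int = 0,
) -> SurvivalFitResult:
    """Random forest on the discretized 3-class survival outcome.

    ``feature_set`` selects the clinical covariates, the 44 heatmap
    features, or both.  The cohort (after discretization) is split
    ``split`` / ``1 - split`` into train and test, stratified by class;
    held-out accuracy and confusion matrix are reported.
    """
    config = config or ForestConfig()
    cols, cats = _feature_columns(feature_set)
    data = discretize_cohort(frame)
    counts = data["survival_class"].value_counts()
    if len(counts) < 3:
        raise ValueError(
            "need all 3 survival classes after discretization; got counts "
            + ", ".join(f"{c}={int(counts.get(c, 0))}" for c in SURVIVAL_CLASSES)
        )
    X = data[cols].to_numpy(dtype=float)
    y = data["survival_class"].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        max_depth=config.max_depth,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    accuracy = float((pred == y_te).mean())
    cm = pd.DataFrame(
        0, index=list(SURVIVAL_CLASSES), columns=list(SURVIVAL_CLASSES)
    )
    for t, p in zip(y_te, pred):
        cm.loc[t, p] += 1
    return SurvivalFitResult(
        forest=forest,
        feature_names=tuple(cols),
        categories=tuple(cats),
        classes=tuple(forest.classes_),
        accuracy=accuracy,
        confusion=cm,
        n_train=len(y_tr),
        n_test=len(y_te),
    )


def split_importance(
    fit: SurvivalFitResult | RandomForestClassifier,
    feature_names: Sequence[str] | None = None,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Split-count feature importance of a trained forest.

    Importance of a feature is the number of internal nodes splitting on
    it, summed over all trees and normalized to sum to 1.  Returns a frame
    with columns ``feature``, ``category``, ``n_splits``, ``importance``,
    sorted descending.
    """
    if isinstance(fit, SurvivalFitResult):
        forest = fit.forest
        feature_names = feature_names or fit.feature_names
        categories = categories or fit.categories
    else:
        forest = fit
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(forest.n_features_in_)]
    n = len(feature_names)
    counts = np.zeros(n, dtype=np.int64)
    for tree in forest.estimators_:
        feats = tree.tree_.feature
        internal = feats[feats >= 0]
        counts += np.bincount(internal, minlength=n)
    total = counts.sum()
    importance = counts / total if total else np.zeros(n)
    frame = pd.DataFrame(
        {
            "feature": list(feature_names),
            "category": list(categories) if categories is not None else "",
            "n_splits": counts,
            "importance": importance,
        }
    )
    return frame.sort_values(
        "importance", ascending=False, kind="stable"
    ).reset_index(drop=True)


# -- Kaplan-Meier and log-rank ---------------------------------------------


@dataclasses.dataclass
class KMCurve:
    """A Kaplan-Meier product-limit curve with 95% confidence band.

    ``times`` is the observed time grid (including 0); ``survival`` the
    right-continuous step estimate S(t); ``at_risk`` and ``observed`` the
    per-time risk-set sizes and event counts.
    """

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s[0] != 1.0 and self.times[0] == 0:
            raise ValueError("S(0) must be 1")
        if (np.diff(s) > 1e-12).any():
            raise ValueError("survival estimate must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(
    durations: Sequence[float],
    events: Sequence[int],
    alpha: float = 0.05,
) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood-variance confidence band
    (lifelines' log-log transform, which keeps the band inside [0, 1])."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    table = kmf.event_table
    return KMCurve(
        times=times,
        survival=surv,
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=float),
        observed=table["observed"].to_numpy(dtype=float),
    )


@dataclasses.dataclass
class MedianSplitResult:
    """Two KM curves split at the feature median, plus the log-rank test.

    ``high`` is the x >= median group (ties go up), ``low`` the x < median
    group; ``overall`` is the all-sample reference curve.
    """

    feature: str
    cutoff: float
    high: KMCurve
    low: KMCurve
    overall: KMCurve
    statistic: float
    p_value: float
    n_high: int
    n_low: int


def median_split_curves(
    durations: Sequence[float],
    events: Sequence[int],
    values: Sequence[float],
    feature: str = "feature",
) -> MedianSplitResult:
    """Compare survival above vs below the sample median of a feature.

    The cutoff is the sample median; records equal to it join the upper
    group.  The two-group log-rank chi-square (1 df) and p-value are
    computed on the raw censored records.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    values = np.asarray(values, dtype=float)
    cutoff = float(np.median(values))
    upper = values >= cutoff
    if upper.all() or not upper.any():
        raise ValueError(
            f"degenerate split: all values fall on one side of the median "
            f"{cutoff} (are all values equal?)"
        )
    result = logrank_test(
        durations[upper], durations[~upper], events[upper], events[~upper]
    )
    return MedianSplitResult(
        feature=feature,
        cutoff=cutoff,
        high=km_estimate(durations[upper], events[upper]),
        low=km_estimate(durations[~upper], events[~upper]),
        overall=km_estimate(durations, events),
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        n_high=int(upper.sum()),
        n_low=int((~upper).sum()),
    )


def export_curve(curve: KMCurve) -> pd.DataFrame:
    """Curve as a (t, S, ci_lower, ci_upper, at_risk, observed) frame."""
    return pd.DataFrame(
        {
            "t": curve.times,
            "survival": curve.survival,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
            "at_risk": curve.at_risk,
            "observed": curve.observed,
        }
    )


def plot_median_split(result: MedianSplitResult, path) -> None:
    """Save a step plot of the two group curves, the all-sample reference
    and the confidence bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve, label, color in (
        (result.high, f"{result.feature} >= {result.cutoff:.3g}", "#c0392b"),
        (result.low, f"{result.feature} < {result.cutoff:.3g}", "#2980b9"),
    ):
        ax.step(curve.times, curve.survival, where="post", label=label, color=color)
        ax.fill_between(
            curve.times, curve.ci_lower, curve.ci_upper,
            step="post", alpha=0.2, color=color,
        )
    ax.step(
        result.overall.times, result.overall.survival,
        where="post", color="black", linestyle=":", label="all cases",
    )
    ax.set_xlabel("months")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    ax.set_title(f"log-rank p = {result.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
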