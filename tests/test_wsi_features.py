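"""44-feature heatmap morphometry and the slide-level random forest."""

import numpy as np
import pytest

from gastroslide.heatmap import Heatmap
from gastroslide.wsi_features import (
    FEATURE_NAMES,
    FeatureVector44,
    ForestConfig,
    classify_slide,
    extract_feature_vector,
    split_cohort,
    threshold_regions,
    train_slide_classifier,
)

from oracles import features_bruteforce, region_props_bruteforce


def heatmap_from(values, tissue=None):
    return Heatmap(values=np.asarray(values, dtype=float), cell_size=64,
                   tissue=tissue)


def random_heatmap(rng, ny=24, nx=24):
    values = rng.uniform(0, 1, (ny, nx))
    # plant a few hot blobs so region features are non-trivial
    for _ in range(rng.integers(1, 4)):
        y, x = rng.integers(0, ny - 6), rng.integers(0, nx - 6)
        h, w = rng.integers(2, 6), rng.integers(2, 6)
        values[y : y + h, x : x + w] = rng.uniform(0.9, 1.0)
    tissue = rng.random((ny, nx)) > 0.15
    values[~tissue] = rng.uniform(0, 1, (~tissue).sum())
    return heatmap_from(values, tissue)


def to_lists(hm):
    values = [
        [None if not np.isfinite(v) else float(v) for v in row]
        for row in hm.values
    ]
    tissue = (
        [[bool(t) for t in row] for row in hm.tissue]
        if hm.tissue is not None
        else [[True] * hm.values.shape[1]] * hm.values.shape[0]
    )
    return values, tissue


class TestThresholdRegions:
    def test_uniform_hot_heatmap_is_one_full_region(self):
        hm = heatmap_from(np.full((6, 9), 0.95))
        regions = threshold_regions(hm, 0.9)
        assert len(regions) == 1
        r = regions.regions[0]
        assert r.area == 54 and r.extent == pytest.approx(1.0)

    def test_square_region_properties(self):
        values = np.zeros((20, 20))
        values[5:15, 5:15] = 0.95
        regions = threshold_regions(heatmap_from(values), 0.9)
        r = regions.regions[0]
        assert r.area == 100
        assert r.extent == pytest.approx(1.0)
        assert r.eccentricity == pytest.approx(0.0)
        assert r.perimeter == 40
        assert r.mean_probability == pytest.approx(0.95)

    def test_matches_bruteforce_region_props(self):
        rng = np.random.default_rng(5)
        hm = random_heatmap(rng)
        regions = threshold_regions(hm, 0.9)
        values, tissue = to_lists(hm)
        binary = [
            [
                tissue[j][i] and values[j][i] is not None and values[j][i] >= 0.9
                for i in range(hm.values.shape[1])
            ]
            for j in range(hm.values.shape[0])
        ]
        vals = [[v or 0.0 for v in row] for row in values]
        oracle = region_props_bruteforce(binary, vals)
        assert len(regions) == len(oracle)
        got = sorted(
            [(r.area, r.perimeter, r.eccentricity, r.extent,
              r.major_axis_length) for r in regions]
        )
        want = sorted(
            [(o["area"], o["perimeter"], o["eccentricity"], o["extent"],
              o["major_axis_length"]) for o in oracle]
        )
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-10)


class TestFeatureVector:
    def test_always_exactly_44_features(self):
        rng = np.random.default_rng(6)
        fv = extract_feature_vector(random_heatmap(rng))
        assert len(fv) == 44
        assert fv.values.shape == (44,)
        assert len(set(FEATURE_NAMES)) == 44

    def test_all_zero_heatmap_gives_all_zero_features(self):
        fv = extract_feature_vector(heatmap_from(np.zeros((10, 10))))
        assert not fv.values.any()

    def test_uniform_095_heatmap_closed_forms(self):
        fv = extract_feature_vector(heatmap_from(np.full((10, 10), 0.95)))
        s = fv.as_series()
        assert s["tumor_area_fraction_p90"] == pytest.approx(1.0)
        assert s["fraction_cells_p90"] == pytest.approx(1.0)
        assert s["mean_malignant_probability"] == pytest.approx(0.95)
        assert s["frac_prob_gt_0.999"] == pytest.approx(0.0)
        assert s["frac_prob_0.9_0.95"] == pytest.approx(1.0)
        assert s["prob_sum"] == pytest.approx(95.0)

    def test_two_region_heatmap_matches_bruteforce(self):
        values = np.full((50, 50), 0.1)
        values[3:15, 3:15] = 0.92
        values[30:35, 30:35] = 0.96
        hm = heatmap_from(values)
        fv = extract_feature_vector(hm)
        oracle = features_bruteforce(*to_lists(hm))
        assert np.allclose(fv.values, oracle, atol=1e-10)

    def test_matches_bruteforce_on_random_heatmaps(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            hm = random_heatmap(rng)
            fv = extract_feature_vector(hm)
            oracle = features_bruteforce(*to_lists(hm))
            assert np.allclose(fv.values, oracle, atol=1e-10)

    def test_probability_bins_sum_to_above_half_fraction(self):
        rng = np.random.default_rng(8)
        hm = random_heatmap(rng)
        fv = extract_feature_vector(hm)
        probs = hm.values[hm.tissue_cells()]
        assert fv.values[36:44].sum() == pytest.approx((probs > 0.5).mean())

    def test_scale_covariance_of_proportions_and_lengths(self):
        """Doubling the grid resolution leaves proportion features nearly
        unchanged, multiplies areas by 4 and lengths by 2."""
        values = np.full((20, 20), 0.2)
        values[4:12, 6:14] = 0.95
        coarse = extract_feature_vector(heatmap_from(values)).as_series()
        fine = extract_feature_vector(
            heatmap_from(np.kron(values, np.ones((2, 2))))
        ).as_series()
        for name in ("tumor_area_fraction_p90", "fraction_cells_p90",
                     "mean_malignant_probability", "prob_mean",
                     "frac_prob_0.9_0.95"):
            assert fine[name] == pytest.approx(coarse[name], rel=0.02)
        assert fine["largest_region_area_p50"] == pytest.approx(
            4 * coarse["largest_region_area_p50"]
        )
        assert fine["largest_region_major_axis_p50"] == pytest.approx(
            2 * coarse["largest_region_major_axis_p50"], rel=0.02
        )

    def test_empty_heatmap_rejected(self):
        hm = heatmap_from(np.full((4, 4), np.nan))
        with pytest.raises(ValueError, match="no tissue"):
            extract_feature_vector(hm)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="44"):
            FeatureVector44(values=np.zeros(43))


@pytest.fixture(scope="module")
def toy_features():
    rng = np.random.default_rng(9)
    X = rng.uniform(0, 1, (60, 44))
    y = np.where(X[:, 1] + X[:, 35] > 1.0, "cancer", "normal")
    return X, y


class TestSlideForest:
    def test_deterministic_under_seed(self, toy_features):
        X, y = toy_features
        a = train_slide_classifier(X, y, ForestConfig(n_estimators=50), seed=3)
        b = train_slide_classifier(X, y, ForestConfig(n_estimators=50), seed=3)
        assert np.array_equal(
            a.forest.predict_proba(X), b.forest.predict_proba(X)
        )

    def test_vote_fractions_match_manual_tree_count(self, toy_features):
        X, y = toy_features
        model = train_slide_classifier(X, y, ForestConfig(n_estimators=3, oob_score=False), seed=0)
        vec = X[7]
        _, probs = classify_slide(model, vec)
        votes = {c: 0 for c in model.classes}
        for tree in model.forest.estimators_:
            leaf_probs = tree.predict_proba(vec[None])[0]
            votes[model.classes[int(np.argmax(leaf_probs))]] += 1
        for c in model.classes:
            assert probs[c] == pytest.approx(votes[c] / 3)

    def test_probabilities_sum_to_one(self, toy_features):
        X, y = toy_features
        model = train_slide_classifier(X, y, ForestConfig(n_estimators=20, oob_score=False), seed=1)
        _, probs = classify_slide(model, X[0])
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_schema_mismatch_rejected(self, toy_features):
        X, y = toy_features
        model = train_slide_classifier(X, y, ForestConfig(n_estimators=10, oob_score=False), seed=1)
        with pytest.raises(ValueError, match="44"):
            classify_slide(model, np.zeros(10))

    def test_single_class_rejected(self):
        X = np.zeros((20, 44))
        with pytest.raises(ValueError, match="2 slide classes"):
            train_slide_classifier(X, ["normal"] * 20)


class TestSplitCohort:
    def test_published_cohort_sizes(self):
        train, test, val = split_cohort(range(763), (0.7, 0.2, 0.1), seed=0)
        assert (len(train), len(test), len(val)) == (534, 153, 76)

    def test_small_cohort_rounding(self):
        train, test, val = split_cohort(range(10), (0.7, 0.2, 0.1), seed=0)
        assert (len(train), len(test), len(val)) == (7, 2, 1)

    @pytest.mark.parametrize("n", [3, 17, 100, 763])
    def test_partition_contract(self, n):
        ids = [f"s{i}" for i in range(n)]
        train, test, val = split_cohort(ids, seed=4)
        combined = train + test + val
        assert sorted(combined) == sorted(ids)
        assert len(set(train) & set(test)) == 0
        assert len(set(train) & set(val)) == 0
        assert len(set(test) & set(val)) == 0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_cohort(range(10), (0.5, 0.2, 0.1))
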