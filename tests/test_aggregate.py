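"""Slide feature counting and the gradient-boosted meta-classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hesubtype.aggregate import (ABSTAIN, MetaModelConfig, SlideAggregator,
                                 count_features, featurize_wsis, train_meta)
from hesubtype.thresholds import ThresholdSet

CLASSES = ("LumA", "LumB", "HER2", "BL")
TAU = ThresholdSet({"LumA": 0.434, "LumB": 0.415, "HER2": 0.481,
                    "BL": 0.424})


def tables_from_scores(scores: dict[str, np.ndarray]) -> dict[str, pd.DataFrame]:
    n = len(next(iter(scores.values())))
    ids = [f"t{i}" for i in range(n)]
    return {cls: pd.DataFrame({"tile_id": ids, "score_target": s,
                               "score_rest": 1 - s})
            for cls, s in scores.items()}


class TestCountFeatures:
    def test_saturated_scores(self):
        tabs = tables_from_scores({c: np.ones(10) if c == "LumA"
                                   else np.zeros(10) for c in CLASSES})
        fv = count_features(tabs, TAU, "w")
        assert fv.counts[0] == 10 and fv.counts[1] == 0
        assert fv.n_tiles == 10

    def test_all_zero_scores(self):
        tabs = tables_from_scores({c: np.zeros(7) for c in CLASSES})
        fv = count_features(tabs, TAU, "w")
        assert list(fv.counts) == [0, 7] * 4

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        scores = {c: rng.random(20) for c in CLASSES}
        fv = count_features(tables_from_scores(scores), TAU, "w")
        for k, cls in enumerate(CLASSES):
            expected = sum(s >= TAU.tau[cls] for s in scores[cls])
            assert fv.counts[2 * k] == expected
            assert fv.counts[2 * k + 1] == 20 - expected

    def test_mismatched_tile_sets_rejected(self):
        tabs = tables_from_scores({c: np.zeros(5) for c in CLASSES})
        tabs["BL"] = tabs["BL"].iloc[:3]
        with pytest.raises(ValueError):
            count_features(tabs, TAU, "w")

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        scores = {c: rng.random(n) for c in CLASSES}
        fv = count_features(tables_from_scores(scores), TAU, "w")
        pairs = fv.counts.reshape(-1, 2)
        assert (pairs.sum(axis=1) == n).all()

    def test_monotone_in_scores(self):
        rng = np.random.default_rng(4)
        scores = {c: rng.random(25) for c in CLASSES}
        fv = count_features(tables_from_scores(scores), TAU, "w")
        bumped = dict(scores)
        bumped["LumA"] = np.clip(scores["LumA"] + 0.2, 0, 1)
        fv2 = count_features(tables_from_scores(bumped), TAU, "w")
        assert fv2.counts[0] >= fv.counts[0]


def separable_features(n_per_class: int, n_tiles: int = 50, seed: int = 0,
                       shuffle_labels: bool = False):
    """Feature rows where count_c dominates for the true class."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls in CLASSES:
        for i in range(n_per_class):
            counts = {}
            for c in CLASSES:
                hit = int(rng.integers(35, n_tiles + 1)) if c == cls \
                    else int(rng.integers(0, 8))
                counts[f"count_{c}"] = hit
                counts[f"count_not_{c}"] = n_tiles - hit
            rows.append({"wsi_id": f"{cls}{i}", **counts,
                         "n_tiles": n_tiles})
            labels.append(cls)
    feats = pd.DataFrame(rows)
    labels = np.array(labels)
    if shuffle_labels:
        labels = rng.permutation(labels)
    return feats, labels


class TestSlideAggregator:
    def test_separable_features_perfect_validation(self):
        feats, labels = separable_features(10)
        agg = SlideAggregator(MetaModelConfig(seed=0)).fit(feats, labels)
        assert (agg.predict(feats) == labels).all()

    def test_deterministic(self):
        feats, labels = separable_features(6)
        p1 = SlideAggregator(MetaModelConfig(seed=5)).fit(feats, labels) \
            .predict_proba(feats)
        p2 = SlideAggregator(MetaModelConfig(seed=5)).fit(feats, labels) \
            .predict_proba(feats)
        assert np.array_equal(p1, p2)

    def test_probabilities_normalized(self):
        feats, labels = separable_features(5)
        agg = SlideAggregator(MetaModelConfig(seed=0)).fit(feats, labels)
        assert np.allclose(agg.predict_proba(feats).sum(axis=1), 1.0,
                           atol=1e-6)

    def test_abstain_on_empty_slides(self):
        feats, labels = separable_features(5)
        agg = SlideAggregator(MetaModelConfig(seed=0)).fit(feats, labels)
        empty = feats.iloc[:2].copy()
        empty["n_tiles"] = 0
        preds = agg.predict(empty)
        assert (preds == ABSTAIN).all()

    def test_shuffled_labels_near_chance(self):
        """Label permutation destroys the feature-label link; held-out
        accuracy must fall inside the permutation null around 0.25."""
        feats, labels = separable_features(12, seed=1, shuffle_labels=True)
        hold, hold_labels = separable_features(12, seed=2)
        agg = SlideAggregator(MetaModelConfig(seed=0)).fit(feats, labels)
        acc = float((agg.predict(hold) == hold_labels).mean())
        # 48 held-out slides at p = 0.25: 4 sigma ~ 0.25
        assert acc < 0.5

    def test_single_class_rejected(self):
        feats, labels = separable_features(4)
        with pytest.raises(ValueError):
            SlideAggregator().fit(feats, np.array(["LumA"] * len(feats)))


def test_featurize_wsis_matches_count_features():
    rng = np.random.default_rng(2)
    rows = []
    for w in ("w1", "w2"):
        for t in range(15):
            row = {"wsi_id": w, "tile_id": f"{w}t{t}"}
            for c in CLASSES:
                row[f"score_{c}"] = rng.random()
            rows.append(row)
    scores = pd.DataFrame(rows)
    feats = featurize_wsis(scores, TAU, CLASSES)
    for w in ("w1", "w2"):
        g = scores[scores["wsi_id"] == w]
        tabs = {c: pd.DataFrame({"tile_id": g["tile_id"],
                                 "score_target": g[f"score_{c}"]})
                for c in CLASSES}
        fv = count_features(tabs, TAU, w)
        row = feats[feats["wsi_id"] == w].iloc[0]
        got = [row[f"count_{c}"] for c in CLASSES]
        assert got == [fv.counts[2 * k] for k in range(4)]


def test_featurize_order_invariance():
    rng = np.random.default_rng(3)
    rows = []
    for w in ("a", "b", "c"):
        for t in range(10):
            row = {"wsi_id": w, "tile_id": f"{w}{t}"}
            row.update({f"score_{c}": rng.random() for c in CLASSES})
            rows.append(row)
    scores = pd.DataFrame(rows)
    f1 = featurize_wsis(scores, TAU, CLASSES)
    f2 = featurize_wsis(scores.sample(frac=1, random_state=0), TAU, CLASSES)
    pd.testing.assert_frame_equal(f1, f2)


def test_train_meta_excludes_empty_slides():
    feats, labels = separable_features(5)
    feats.loc[0, "n_tiles"] = 0
    model = train_meta(feats, labels, MetaModelConfig(seed=0))
    assert hasattr(model, "model_")
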