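"""Slide-level aggregation: 8-count feature vectors and the
gradient-boosted meta-classifier.

Each WSI is summarized by eight tile counts — for each subtype c, the
number of selected tumor tiles whose one-vs-rest target score meets that
classifier's threshold (count_c) and its complement (count_not_c =
n_tiles - count_c). The four classifiers' two-score softmax outputs sum to
one, so thresholding the rest score independently would be redundant; the
complement is used. A multi-class gradient-boosted tree model (XGBoost)
maps the 8 counts to the subtype label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin

from .thresholds import ThresholdSet

__all__ = [
    "SlideFeatureVector",
    "MetaModelConfig",
    "count_features",
    "featurize_wsis",
    "SlideAggregator",
    "train_meta",
    "predict_wsi",
    "ABSTAIN",
    "FEATURE_COLUMNS",
]

ABSTAIN = "abstain"


def feature_columns(class_names) -> list[str]:
    cols = []
    for c in class_names:
        cols += [f"count_{c}", f"count_not_{c}"]
    return cols


FEATURE_COLUMNS = feature_columns(("LumA", "LumB", "HER2", "BL"))


@dataclass
class SlideFeatureVector:
    """Eight tile counts for one WSI, ordered (c, not-c) per subtype in the
    class order used throughout the cohort. ``n_tiles = 0`` marks a WSI
    with no tumor tiles: downstream prediction must abstain."""

    wsi_id: str
    counts: np.ndarray
    n_tiles: int
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2 * len(self.class_names),):
            raise ValueError("counts must hold a (c, not-c) pair per class")
        pairs = self.counts.reshape(-1, 2)
        if self.n_tiles > 0 and not np.all(pairs.sum(axis=1) == self.n_tiles):
            raise ValueError("count_c + count_not_c must equal n_tiles "
                             "for every class")

    @property
    def abstain(self) -> bool:
        return self.n_tiles == 0


@dataclass(frozen=True)
class MetaModelConfig:
    """Gradient-boosting hyperparameters (unconstrained by the method
    itself; exposed in config)."""

    n_rounds: int = 400
    max_depth: int = 3
    learning_rate: float = 0.05
    early_stopping_rounds: int = 20
    min_child_weight: float = 0.0
    colsample_bytree: float = 0.25
    subsample: float = 0.63
    seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1 or self.max_depth < 1 or self.learning_rate <= 0:
            raise ValueError("meta-model hyperparameters must be positive")


def count_features(score_tables: dict[str, pd.DataFrame], tau: ThresholdSet,
                   wsi_id: str = "wsi") -> SlideFeatureVector:
    """Count, per class, the tiles whose target score meets the class
    threshold. All four tables must cover exactly the same tile set."""
    class_names = tuple(score_tables)
    tile_sets = [frozenset(t["tile_id"]) for t in score_tables.values()]
    if any(s != tile_sets[0] for s in tile_sets[1:]):
        raise ValueError("score tables cover different tile sets")
    n_tiles = len(tile_sets[0])
    counts = []
    for cls in class_names:
        t = tau.tau[cls]
        c = int(np.sum(score_tables[cls]["score_target"].to_numpy() >= t))
        counts += [c, n_tiles - c]
    return SlideFeatureVector(wsi_id, np.array(counts), n_tiles, class_names)


def featurize_wsis(scores: pd.DataFrame, tau: ThresholdSet,
                   class_names) -> pd.DataFrame:
    """Vectorized per-WSI counting over a long score table with columns
    ``wsi_id``, ``tile_id`` and ``score_<class>`` per class. Returns one
    row per WSI: the 8 counts plus ``n_tiles``."""
    rows = []
    for wsi_id, g in scores.groupby("wsi_id", sort=True):
        n = len(g)
        counts = []
        for cls in class_names:
            c = int(np.sum(g[f"score_{cls}"].to_numpy() >= tau.tau[cls]))
            counts += [c, n - c]
        rows.append([wsi_id, *counts, n])
    return pd.DataFrame(rows, columns=["wsi_id",
                                       *feature_columns(class_names),
                                       "n_tiles"])


class SlideAggregator(BaseEstimator, ClassifierMixin):
    """Multi-class gradient-boosted meta-classifier over the 8 counts.

    ``fit`` holds out an inner validation fraction (default 20%) for
    boosting-round selection via early stopping. ``include_fractions``
    optionally appends n_tiles-normalized count fractions to the raw-count
    features (off by default: raw counts are the canonical features even
    though they confound WSI size).
    """

    def __init__(self, config: MetaModelConfig | None = None,
                 val_fraction: float = 0.2,
                 include_fractions: bool = False):
        self.config = config
        self.val_fraction = val_fraction
        self.include_fractions = include_fractions

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        cols = feature_columns(self.class_names_)
        X = features[cols].to_numpy(dtype=float)
        if self.include_fractions:
            n = features["n_tiles"].to_numpy(dtype=float)[:, None]
            X = np.hstack([X, X / np.maximum(n, 1.0)])
        return X

    def fit(self, features: pd.DataFrame, y):
        cfg = self.config or MetaModelConfig()
        y = np.asarray(y).astype(str)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to train")
        self.class_names_ = tuple(
            c for c in ("LumA", "LumB", "HER2", "BL") if
            f"count_{c}" in features.columns) or tuple(
            c.removeprefix("count_") for c in features.columns
            if c.startswith("count_") and not c.startswith("count_not_"))
        y_idx = np.searchsorted(self.classes_, y)
        X = self._matrix(features)

        # Per-class validation allocation: round val_fraction of each class
        # into the validation fold but always keep >= 1 training sample per
        # class, so small meta sets (a handful of slides per class) work.
        rng = np.random.default_rng(cfg.seed)
        va_parts = []
        for k in range(len(self.classes_)):
            members = np.flatnonzero(y_idx == k)
            if len(members) == 0:
                raise ValueError(f"class {self.classes_[k]!r} missing from "
                                 "the meta training data")
            v = min(int(round(self.val_fraction * len(members))),
                    len(members) - 1)
            if v > 0:
                va_parts.append(rng.choice(members, size=v, replace=False))
        va = np.sort(np.concatenate(va_parts)) if va_parts else np.array([], int)
        tr = np.setdiff1d(np.arange(len(X)), va)
        if len(np.unique(y_idx[tr])) < len(self.classes_):
            raise ValueError("a class is missing from the training fold")
        params = {
            "objective": "multi:softprob",
            "num_class": len(self.classes_),
            "max_depth": cfg.max_depth,
            "eta": cfg.learning_rate,
            "seed": cfg.seed,
            "nthread": 1,
            "eval_metric": "mlogloss",
            # tiny slide cohorts: the default leaf hessian floor of 1
            # blocks all splits when a class holds a handful of slides,
            # and column subsampling makes the ensemble spread over
            # redundant count features instead of one fragile cut
            "min_child_weight": cfg.min_child_weight,
            "colsample_bytree": cfg.colsample_bytree,
            "subsample": cfg.subsample,
        }
        dtrain = xgb.DMatrix(X[tr], label=y_idx[tr])
        if len(va) > 0:
            dval = xgb.DMatrix(X[va], label=y_idx[va])
            self.model_ = xgb.train(
                params, dtrain, num_boost_round=cfg.n_rounds,
                evals=[(dval, "val")],
                early_stopping_rounds=cfg.early_stopping_rounds,
                verbose_eval=False)
        else:
            self.model_ = xgb.train(params, dtrain,
                                    num_boost_round=cfg.n_rounds)
        score = self.model_.get_score(importance_type="gain")
        n_feat = X.shape[1]
        self.feature_importances_ = np.array(
            [score.get(f"f{i}", 0.0) for i in range(n_feat)])
        return self

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        X = self._matrix(features)
        best = getattr(self.model_, "best_iteration", None)
        it = (0, best + 1) if best is not None else (0, 0)
        return self.model_.predict(xgb.DMatrix(X), iteration_range=it)

    def predict(self, features: pd.DataFrame):
        """Subtype labels; WSIs with zero tumor tiles get the abstain
        marker instead of a label."""
        proba = self.predict_proba(features)
        labels = self.classes_[proba.argmax(axis=1)].astype(object)
        if "n_tiles" in features.columns:
            labels[features["n_tiles"].to_numpy() == 0] = ABSTAIN
        return np.asarray(labels)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("SlideAggregator is not fitted")


def train_meta(features: pd.DataFrame, labels,
               cfg: MetaModelConfig | None = None,
               val_fraction: float = 0.2) -> SlideAggregator:
    """Train the slide-level meta-classifier with an inner 80/20
    train/validation split for round selection."""
    usable = features["n_tiles"].to_numpy() > 0
    agg = SlideAggregator(config=cfg, val_fraction=val_fraction)
    return agg.fit(features[usable], np.asarray(labels)[usable])


def predict_wsi(model: SlideAggregator, features: pd.DataFrame,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Labels (or abstain markers) plus the 4-class probability rows."""
    return model.predict(features), model.predict_proba(features)
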