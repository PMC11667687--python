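"""Tile classifiers: the binary tumor/non-tumor model and the four
one-vs-rest subtype models share one training/inference contract.

:class:`TileClassifier` follows the scikit-learn estimator API: ``fit``
takes an (N, H, W, 3) uint8 tile stack and a label vector, trains the
configured backbone with Adam on softmax cross-entropy with random
flip/rotate augmentation, tracks per-epoch train/validation loss, and
restores the minimum-validation-loss checkpoint; ``predict_proba`` is
deterministic (no dropout, no augmentation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .backbones import Adam, make_backbone

__all__ = [
    "TrainConfig",
    "TileClassifier",
    "score_tiles",
    "save_model",
    "load_model",
    "TUMOR_PRESET",
    "OVR_PRESET",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are tuned for the "tiny" backbone trained from scratch on
    small synthetic tiles. ``TUMOR_PRESET`` and ``OVR_PRESET`` preserve the
    settings used with large pretrained backbones (batch 64 / lr 1e-5 and
    batch 128 / lr 5e-6, both with dropout 0.33).
    """

    batch_size: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.33
    max_epochs: int = 10
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    augment: tuple[str, ...] = ("hflip", "vflip", "rotate90")
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


TUMOR_PRESET = TrainConfig(batch_size=64, learning_rate=1e-5, dropout=0.33)
OVR_PRESET = TrainConfig(batch_size=128, learning_rate=5e-6, dropout=0.33)


def _augment_batch(x: np.ndarray, flags, rng: np.random.Generator) -> np.ndarray:
    """Per-sample random horizontal/vertical flips and 90-degree rotations."""
    x = x.copy()
    n = x.shape[0]
    if "hflip" in flags:
        idx = rng.random(n) < 0.5
        x[idx] = x[idx, :, ::-1]
    if "vflip" in flags:
        idx = rng.random(n) < 0.5
        x[idx] = x[idx, ::-1]
    if "rotate90" in flags:
        k = rng.integers(0, 4, n)
        for r in range(1, 4):
            idx = np.where(k == r)[0]
            if idx.size:
                x[idx] = np.rot90(x[idx], k=r, axes=(1, 2))
    return x


def _prep(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=np.float32) / 255.0) - 0.5


class TileClassifier(BaseEstimator, ClassifierMixin):
    """Backbone-agnostic tile classifier.

    Parameters
    ----------
    backbone : registered backbone name (default "tiny").
    config : TrainConfig; None uses the defaults.

    Fitted attributes: ``classes_`` (label order of predict_proba
    columns), ``model_`` (the trained backbone), ``history_`` (per-epoch
    train/val loss and val accuracy), ``best_epoch_``.
    """

    def __init__(self, backbone: str = "tiny", config: TrainConfig | None = None):
        self.backbone = backbone
        self.config = config

    def fit(self, X, y):
        cfg = self.config or TrainConfig()
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be an (N, H, W, 3) tile stack")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty tile set")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to train")
        y_idx = np.searchsorted(self.classes_, y)

        rng = np.random.default_rng(cfg.seed)
        if cfg.val_fraction > 0 and len(X) >= 10:
            tr, va = train_test_split(
                np.arange(len(X)), test_size=cfg.val_fraction,
                random_state=cfg.seed, stratify=y_idx)
        else:
            tr = va = np.arange(len(X))
        Xtr, ytr = X[tr], y_idx[tr]
        Xva, yva = _prep(X[va]), y_idx[va]

        model = make_backbone(self.backbone, X.shape[1:],
                              len(self.classes_), cfg.dropout, cfg.seed)
        opt = Adam(model.params, lr=cfg.learning_rate)

        self.history_ = []
        best = (np.inf, None, -1)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = _augment_batch(Xtr[idx], cfg.augment, rng)
                loss, grads = model.loss_and_grads(_prep(xb), ytr[idx],
                                                   train=True, rng=rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch {start // cfg.batch_size}: {loss}")
                opt.step(model.params, grads)
                losses.append(loss)
            val_probs = self._batched_proba(model, Xva, prepped=True)
            val_loss = float(-np.mean(np.log(
                val_probs[np.arange(len(yva)), yva] + 1e-12)))
            val_acc = float(np.mean(val_probs.argmax(axis=1) == yva))
            self.history_.append({"epoch": epoch,
                                  "train_loss": float(np.mean(losses)),
                                  "val_loss": val_loss, "val_acc": val_acc})
            if val_loss < best[0]:
                best = (val_loss, model.get_weights(), epoch)
        if best[1] is not None:
            model.set_weights(best[1])
        self.best_epoch_ = best[2]
        self.model_ = model
        return self

    @staticmethod
    def _batched_proba(model, X, prepped=False, batch=256):
        out = []
        for start in range(0, len(X), batch):
            xb = X[start:start + batch]
            out.append(model.predict_proba(xb if prepped else _prep(xb)))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X):
        self._check_fitted()
        X = np.asarray(X)
        if X.shape[1:] != tuple(self.model_.input_shape):
            raise ValueError(f"tile shape {X.shape[1:]} does not match the "
                             f"trained input {self.model_.input_shape}")
        return self._batched_proba(self.model_, X)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("TileClassifier is not fitted")


def score_tiles(model: TileClassifier, tiles: np.ndarray,
                tile_ids, target_class) -> pd.DataFrame:
    """Score a tile stack; one row per tile with the softmax pair
    (score_target, score_rest) for the given target class."""
    probs = model.predict_proba(tiles)
    target_col = int(np.where(model.classes_ == target_class)[0][0])
    score_target = probs[:, target_col]
    return pd.DataFrame({
        "tile_id": list(tile_ids),
        "score_target": score_target,
        "score_rest": 1.0 - score_target,
    })


def save_model(model: TileClassifier, path: str | Path) -> None:
    """Checkpoint: weights as .npz plus a JSON sidecar (config, classes,
    tile size)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.model_.params)
    cfg = model.config or TrainConfig()
    sidecar = {
        "backbone": model.backbone,
        "config": asdict(cfg),
        "classes": [str(c) for c in model.classes_],
        "input_shape": list(model.model_.input_shape),
        "best_epoch": model.best_epoch_,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TileClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = sidecar["config"]
    cfg_d["augment"] = tuple(cfg_d["augment"])
    cfg = TrainConfig(**cfg_d)
    clf = TileClassifier(backbone=sidecar["backbone"], config=cfg)
    clf.classes_ = np.array(sidecar["classes"])
    model = make_backbone(sidecar["backbone"],
                          tuple(sidecar["input_shape"]),
                          len(clf.classes_), cfg.dropout, cfg.seed)
    with np.load(path.with_suffix(".npz")) as data:
        model.set_weights({k: data[k] for k in data.files})
    clf.model_ = model
    clf.best_epoch_ = sidecar["best_epoch"]
    clf.history_ = []
    return clf
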