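"""Macenko stain estimation and color normalization.

H&E color variation between scanners and labs is removed by expressing each
pixel in optical density (OD = -log of the transmitted light fraction,
linear in stain concentration by the Beer-Lambert law), estimating the two
stain vectors from the extreme angles of the OD point cloud in its top-2
singular plane, and re-rendering each tile's stain concentrations through a
common reference profile.

Conventions (the original method's usual settings, all configurable):
``beta = 0.15`` OD threshold for background exclusion, ``alpha = 1`` so the
stain vectors sit at the 1st/99th percentile angles, concentration scale at
the 99th percentile. OD uses a +1 offset before the log so that a pixel
value of 255 maps to a small positive OD rather than -log(0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "StainProfile",
    "estimate_stain",
    "normalize_tile",
    "build_reference",
    "MacenkoNormalizer",
    "InsufficientTissueError",
    "DegenerateStainError",
    "EmptyReferenceError",
    "angle_between_deg",
]

logger = logging.getLogger(__name__)

BETA_DEFAULT = 0.15
ALPHA_DEFAULT = 1.0
CONCENTRATION_PERCENTILE = 99.0
MIN_TISSUE_PIXELS = 100
WHITE_MEAN_MIN = 240.0


class InsufficientTissueError(ValueError):
    """Too few pixels above the OD background threshold."""


class DegenerateStainError(ValueError):
    """The OD cloud does not span two distinguishable stain directions."""


class EmptyReferenceError(ValueError):
    """No tumor tiles available to build a reference mosaic."""


@dataclass
class StainProfile:
    """3x2 unit-column stain matrix (hematoxylin first, identified as the
    column with the larger blue-channel OD) plus per-stain robust
    concentration scales."""

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        if np.any(self.max_concentrations <= 0):
            raise ValueError("max_concentrations must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainProfile":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["stain_matrix"]),
                   np.array(d["max_concentrations"]))


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Optical density per channel: -log((pixel + 1) / 256)."""
    return -np.log((np.asarray(image, dtype=float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    img = 256.0 * np.exp(-od) - 1.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                      -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def nonneg_concentrations(S: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Per-pixel nonnegative least squares ``min ||S c - od||, c >= 0`` for
    a 3x2 stain matrix, solved in closed form and vectorized.

    The unconstrained normal-equation solution is used where feasible;
    otherwise the better of the two single-stain axis solutions (the other
    concentration clamped to zero) is taken — exhaustive over the active
    sets of a 2-variable NNLS problem.
    """
    od = np.asarray(od, dtype=float).reshape(-1, 3)
    A = S.T @ S                       # (2, 2)
    b = od @ S                        # (N, 2)
    c_un = np.linalg.solve(A, b.T).T  # unconstrained solution
    s11, s22 = A[0, 0], A[1, 1]
    c1 = np.maximum(b[:, 0] / s11, 0.0)   # stain 1 only
    c2 = np.maximum(b[:, 1] / s22, 0.0)   # stain 2 only
    # Residual^2 up to the constant ||od||^2: q(c) = c.A.c - 2 c.b
    def q(cc):
        return (cc[:, 0] ** 2 * A[0, 0] + cc[:, 1] ** 2 * A[1, 1]
                + 2 * cc[:, 0] * cc[:, 1] * A[0, 1]
                - 2 * (cc[:, 0] * b[:, 0] + cc[:, 1] * b[:, 1]))
    cand1 = np.stack([c1, np.zeros_like(c1)], axis=1)
    cand2 = np.stack([np.zeros_like(c2), c2], axis=1)
    pick2 = q(cand2) < q(cand1)
    best_axis = np.where(pick2[:, None], cand2, cand1)
    feasible = np.all(c_un >= 0, axis=1)
    return np.where(feasible[:, None], c_un, best_axis)


def estimate_stain(image: np.ndarray, beta: float = BETA_DEFAULT,
                   alpha: float = ALPHA_DEFAULT) -> StainProfile:
    """Estimate an image's stain profile by the singular-plane /
    percentile-angle construction.

    Raises :class:`InsufficientTissueError` if fewer than 100 pixels exceed
    the OD background threshold, and :class:`DegenerateStainError` if the
    extreme-angle directions are separated by less than 1 degree (e.g. a
    single-stain image with a rank-1 OD cloud).
    """
    od = rgb_to_od(image).reshape(-1, 3)
    keep = np.linalg.norm(od, axis=1) > beta
    if int(keep.sum()) < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {int(keep.sum())} pixels above OD {beta}")
    X = od[keep]

    _, sv, Vt = np.linalg.svd(X, full_matrices=False)
    if sv[1] < 0.02 * sv[0]:
        raise DegenerateStainError("OD cloud is effectively rank-1 "
                                   "(single stain)")
    V = Vt[:2].T                      # (3, 2) plane basis
    # Orient basis vectors toward positive OD so angles don't wrap.
    for j in range(2):
        if V[:, j].sum() < 0:
            V[:, j] = -V[:, j]
    proj = X @ V
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    if np.degrees(hi - lo) < 1.0:
        raise DegenerateStainError("extreme-angle gap below 1 degree")
    v_lo = V @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = V @ np.array([np.cos(hi), np.sin(hi)])

    vecs = []
    for v in (v_lo, v_hi):
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n < 1e-8:
            raise DegenerateStainError("stain direction collapsed to zero")
        vecs.append(v / n)
    # Hematoxylin-like vector (larger blue-channel OD) first.
    if vecs[0][2] < vecs[1][2]:
        vecs = [vecs[1], vecs[0]]
    S = np.stack(vecs, axis=1)
    if angle_between_deg(S[:, 0], S[:, 1]) < 1.0:
        raise DegenerateStainError("estimated stain vectors are collinear")

    C = nonneg_concentrations(S, X)
    max_c = np.percentile(C, CONCENTRATION_PERCENTILE, axis=0)
    max_c = np.maximum(max_c, 1e-6)
    return StainProfile(S, max_c)


def is_white(image: np.ndarray) -> bool:
    return bool(np.all(np.asarray(image, dtype=float)
                       .reshape(-1, 3).mean(axis=0) > WHITE_MEAN_MIN))


def normalize_tile(image: np.ndarray, reference: StainProfile,
                   beta: float = BETA_DEFAULT,
                   alpha: float = ALPHA_DEFAULT) -> np.ndarray:
    """Map a tile's colors onto the reference stain profile.

    Concentrations are computed against the tile's own estimated stain
    matrix, rescaled so each stain's 99th percentile matches the
    reference's scale, then re-rendered through the reference stain matrix.
    Near-white tiles are passed through unchanged (logged skip); other
    estimation failures propagate.
    """
    image = np.asarray(image)
    if is_white(image):
        logger.info("white tile passed through without normalization")
        return image.copy()
    profile = estimate_stain(image, beta=beta, alpha=alpha)
    od = rgb_to_od(image)
    h, w = od.shape[:2]
    C = nonneg_concentrations(profile.stain_matrix, od)
    C = C * (reference.max_concentrations / profile.max_concentrations)
    od_new = (C @ reference.stain_matrix.T).reshape(h, w, 3)
    return od_to_rgb(od_new)


def build_reference(manifest: pd.DataFrame, n_wsis: int = 256,
                    rng: np.random.Generator | int | None = None,
                    beta: float = BETA_DEFAULT,
                    alpha: float = ALPHA_DEFAULT,
                    ) -> tuple[np.ndarray, StainProfile]:
    """Build a reference mosaic: one uniformly chosen tumor tile from each
    of ``n_wsis`` uniformly chosen WSIs (without replacement), laid out
    row-major on a near-square grid, plus the mosaic's estimated profile.

    If fewer WSIs carry tumor tiles, all of them are used (logged).
    """
    rng = np.random.default_rng(rng)
    tumor = manifest[manifest["tissue_class"] == "tumor"]
    if len(tumor) == 0:
        raise EmptyReferenceError("manifest contains no tumor tiles")
    wsis = np.sort(tumor["wsi_id"].unique())
    if len(wsis) < n_wsis:
        logger.info("only %d WSIs with tumor tiles available (requested %d); "
                    "using all", len(wsis), n_wsis)
        chosen = wsis
    else:
        chosen = rng.choice(wsis, size=n_wsis, replace=False)
    tiles = []
    for wsi in chosen:
        pool = tumor[tumor["wsi_id"] == wsi].sort_values("tile_id")
        row = pool.iloc[rng.integers(len(pool))]
        tiles.append(tifffile.imread(row["path"]))
    t = tiles[0].shape[0]
    k = len(tiles)
    ncol = int(np.ceil(np.sqrt(k)))
    nrow = int(np.ceil(k / ncol))
    mosaic = np.full((nrow * t, ncol * t, 3), 255, dtype=np.uint8)
    for i, tile in enumerate(tiles):
        r, c = divmod(i, ncol)
        mosaic[r * t:(r + 1) * t, c * t:(c + 1) * t] = tile
    return mosaic, estimate_stain(mosaic, beta=beta, alpha=alpha)


class MacenkoNormalizer(BaseEstimator, TransformerMixin):
    """Stain-color normalizer with the scikit-learn transformer contract.

    ``fit(X)`` estimates the reference stain profile from a reference image
    (or takes a precomputed :class:`StainProfile` via ``reference``);
    ``transform(X)`` normalizes a single HxWx3 tile or an (N, H, W, 3)
    stack onto that reference.
    """

    def __init__(self, beta: float = BETA_DEFAULT, alpha: float = ALPHA_DEFAULT,
                 reference: StainProfile | None = None):
        self.beta = beta
        self.alpha = alpha
        self.reference = reference

    def fit(self, X=None, y=None):
        if self.reference is not None:
            self.profile_ = self.reference
        else:
            if X is None:
                raise ValueError("fit needs a reference image when no "
                                 "precomputed profile is given")
            self.profile_ = estimate_stain(np.asarray(X), beta=self.beta,
                                           alpha=self.alpha)
        return self

    def transform(self, X):
        if not hasattr(self, "profile_"):
            raise RuntimeError("MacenkoNormalizer is not fitted")
        X = np.asarray(X)
        if X.ndim == 3:
            return normalize_tile(X, self.profile_, self.beta, self.alpha)
        return np.stack([normalize_tile(x, self.profile_, self.beta,
                                        self.alpha) for x in X])
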