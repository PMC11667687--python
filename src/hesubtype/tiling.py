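"""Tissue detection, tile-grid extraction and heatmap reconstruction.

A whole-slide image is processed as a regular grid of fixed-size square
tiles at a target resolution (default 512 px at 0.5 microns/pixel, i.e.
"20x"). Tiles may overlap (the stride is ``tile_px - overlap_px``); partial
tiles at the right/bottom edges are dropped, and tiles whose tissue
fraction falls below a threshold are excluded.

Inputs are assumed to be already at the target resolution; an optional
integer downscale is supported for plain rasters. Full pyramid resampling
of vendor formats is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.color import rgb2hsv

__all__ = [
    "TileGridConfig",
    "TileRecord",
    "detect_tissue",
    "make_grid",
    "extract_tiles",
    "stitch_heatmap",
    "read_image",
]


@dataclass(frozen=True)
class TileGridConfig:
    """Tile-grid geometry and tissue filtering.

    ``overlap_px`` is 0 for ordinary extraction; 64 is used to densify
    sampling for a minority class.
    """

    tile_px: int = 512
    target_mpp: float = 0.5
    overlap_px: int = 0
    min_tissue_fraction: float = 0.5

    def __post_init__(self):
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")
        if not 0 <= self.overlap_px < self.tile_px:
            raise ValueError("overlap_px must satisfy 0 <= overlap < tile_px")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must lie in [0, 1]")

    @property
    def stride(self) -> int:
        return self.tile_px - self.overlap_px


@dataclass(frozen=True)
class TileRecord:
    """One grid tile: 0-based top-left corner, half-open footprint
    [x, x+tile_px) x [y, y+tile_px) on the target-resolution raster."""

    wsi_id: str
    tile_id: str
    x: int
    y: int
    tissue_fraction: float
    path: str = ""


# Tissue rule: a pixel is tissue if it is both colored (HSV saturation
# above a floor) and not near-white. Thresholds are configurable knobs of
# detect_tissue; the defaults suffice for H&E material and catch marker ink
# and folds as well.
SATURATION_MIN = 0.05
BRIGHTNESS_MAX = 235.0


def detect_tissue(image: np.ndarray, saturation_min: float = SATURATION_MIN,
                  brightness_max: float = BRIGHTNESS_MAX) -> np.ndarray:
    """Binary tissue mask of an RGB image (same height/width)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    sat = rgb2hsv(image)[..., 1]
    mean_rgb = image.astype(float).mean(axis=2)
    return (sat > saturation_min) & (mean_rgb < brightness_max)


def make_grid(image_dims: tuple[int, int], mask: np.ndarray | None,
              cfg: TileGridConfig, wsi_id: str = "wsi") -> list[TileRecord]:
    """Place tiles on the stride grid and filter by tissue fraction.

    ``image_dims`` is (height, width). Positions are x, y in
    {0, stride, 2*stride, ...} with the full footprint inside the image;
    an image smaller than one tile yields an empty list.
    """
    h, w = image_dims
    t, s = cfg.tile_px, cfg.stride
    records: list[TileRecord] = []
    if t > h or t > w:
        return records
    integral = None
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ValueError("mask shape must match image_dims")
        integral = np.pad(np.cumsum(np.cumsum(mask, 0), 1), ((1, 0), (1, 0)))
    i = 0
    for y in range(0, h - t + 1, s):
        for x in range(0, w - t + 1, s):
            if integral is None:
                frac = 1.0
            else:
                total = (integral[y + t, x + t] - integral[y, x + t]
                         - integral[y + t, x] + integral[y, x])
                frac = float(total) / (t * t)
            if frac >= cfg.min_tissue_fraction:
                records.append(TileRecord(wsi_id, f"{wsi_id}_T{i:05d}",
                                          x, y, frac))
                i += 1
    return records


def extract_tiles(image: np.ndarray, records: list[TileRecord],
                  cfg: TileGridConfig, out_dir: str | Path) -> pd.DataFrame:
    """Crop the recorded footprints and write uncompressed TIFF tiles plus
    a manifest CSV (columns mirroring TileRecord)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = cfg.tile_px
    rows = []
    for rec in records:
        tile = image[rec.y:rec.y + t, rec.x:rec.x + t]
        path = out_dir / f"{rec.tile_id}.tiff"
        tifffile.imwrite(path, tile, compression=None)
        rows.append((rec.wsi_id, rec.tile_id, rec.x, rec.y,
                     rec.tissue_fraction, str(path)))
    df = pd.DataFrame(rows, columns=["wsi_id", "tile_id", "x", "y",
                                     "tissue_fraction", "path"])
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df


def _score_to_rgb(score: np.ndarray) -> np.ndarray:
    """Green -> yellow -> red ramp: 0 maps to (0,255,0), 0.5 to
    (255,255,0), 1 to (255,0,0)."""
    r = np.clip(2.0 * score, 0.0, 1.0) * 255.0
    g = np.clip(2.0 * (1.0 - score), 0.0, 1.0) * 255.0
    b = np.zeros_like(r)
    return np.stack([r, g, b], axis=-1)


def stitch_heatmap(tile_records: list[TileRecord], scores, image_dims,
                   tile_px: int = 512, downscale: int = 1) -> np.ndarray:
    """Reconstruct a slide-sized RGB overlay coloring each tile footprint
    by its score; overlapping footprints are averaged in score space."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(tile_records):
        raise ValueError("one score per tile record is required")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    h, w = image_dims
    hd, wd = h // downscale, w // downscale
    acc = np.zeros((hd, wd))
    cnt = np.zeros((hd, wd))
    t = max(tile_px // downscale, 1)
    for rec, s in zip(tile_records, scores):
        y, x = rec.y // downscale, rec.x // downscale
        acc[y:y + t, x:x + t] += s
        cnt[y:y + t, x:x + t] += 1.0
    mean = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    rgb = _score_to_rgb(mean)
    rgb[cnt == 0] = 255.0  # uncovered background stays white
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def read_image(path: str | Path, level_mpp: float | None = None) -> np.ndarray:
    """Read a single-resolution TIFF/PNG raster; for a pyramidal TIFF take
    the first (highest-resolution) level."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            return tf.series[0].levels[0].asarray() if tf.series[0].levels \
                else tf.asarray()
    import imageio.v3 as iio
    return iio.imread(path)
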