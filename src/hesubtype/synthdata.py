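"""Synthetic H&E-like cohort generation.

Emulates the structure of a multi-center breast-cancer slide cohort —
patients carrying one or more whole-slide images (WSIs), each WSI a bag of
tiles mixing tumor tissue with stroma, normal epithelium, white background,
marker ink and fold artifacts — so that every downstream stage (tissue
detection, stain normalization, tumor filtering, one-vs-rest subtype
classification, slide aggregation) can be trained and tested against known
generating parameters.

Tiles are rendered through the Beer–Lambert law: an RGB pixel is
``255 * exp(-S @ c)`` where ``S`` is the 3x2 optical-density stain matrix
(columns = hematoxylin, eosin unit vectors) and ``c`` the per-pixel stain
concentrations. Hematoxylin concentration is a field of Gaussian nuclear
blobs; eosin is a smooth background. The four molecular-subtype labels are
planted as monotone shifts of nuclear-blob density and radius, scaled by a
single ``signal_strength`` knob (0 = no signal, labels carry no
information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CohortSpec",
    "SyntheticTile",
    "TileParams",
    "DEFAULT_STAIN_MATRIX",
    "DEFAULT_CLASS_NAMES",
    "TISSUE_CLASSES",
    "render_tile",
    "generate_cohort",
    "load_tile",
    "load_tiles",
    "DegenerateStainError",
    "EmptyCohortError",
]

# Conventional H&E optical-density vectors (hematoxylin, eosin), unit norm.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.65, 0.07],
     [0.70, 0.99],
     [0.29, 0.11]]
)
DEFAULT_STAIN_MATRIX /= np.linalg.norm(DEFAULT_STAIN_MATRIX, axis=0)

DEFAULT_CLASS_NAMES = ("LumA", "LumB", "HER2", "BL")

TISSUE_CLASSES = ("tumor", "stroma", "epithelium", "white", "marker", "fold")

# Non-tumor composition (fractions of the non-tumor mass). Stroma dominates,
# mirroring the observation that folded tissue and epithelium tiles are far
# rarer than plain stroma on real slides.
_NON_TUMOR_MIX = {
    "stroma": 0.55,
    "epithelium": 0.20,
    "white": 0.15,
    "marker": 0.05,
    "fold": 0.05,
}

# Per-class monotone offsets in {-1, -1/3, 1/3, 1}: class k shifts nuclear
# density by 0.6*s*offset and radius by 0.25*s*offset (s = signal_strength).
_CLASS_OFFSETS = np.array([-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0])
_DENSITY_GAIN = 0.75
_RADIUS_GAIN = 0.25


class DegenerateStainError(ValueError):
    """Stain matrix columns are non-unit or (near-)collinear."""


class EmptyCohortError(ValueError):
    """Cohort specification yields zero patients or tiles."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``signal_strength`` controls the separation of the subtype-specific
    texture parameters; 0 plants no label information, 1 (the default used
    throughout the test suite) gives a strongly learnable signal.
    """

    n_patients_per_class: int = 20
    wsis_per_patient: int = 1
    tiles_per_wsi: int = 60
    tumor_fraction: float = 0.7
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    signal_strength: float = 1.0
    stain_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())
    noise_sd: float = 1.0
    tile_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if len(self.class_names) != 4 or len(set(self.class_names)) != 4:
            raise ValueError("class_names must contain exactly 4 unique labels")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValueError("signal_strength and noise_sd must be nonnegative")
        _validate_stain_matrix(np.asarray(self.stain_matrix, dtype=float))

    @property
    def n_tiles_total(self) -> int:
        return (self.n_patients_per_class * len(self.class_names)
                * self.wsis_per_patient * self.tiles_per_wsi)


@dataclass
class TileParams:
    """Generating parameters of one tile (the ground-truth oracle)."""

    tissue_class: str
    subtype: str | None
    blob_density: float          # expected nuclei per 64x64-pixel area
    blob_radius: float           # Gaussian sigma of a nucleus, pixels
    blob_amplitude: float = 1.1  # peak hematoxylin concentration per nucleus
    eosin_level: float = 0.25    # smooth eosin background concentration
    concentration_scale: float = 1.0  # >1 darkens (fold artifacts)
    stain_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())
    noise_sd: float = 1.0


@dataclass
class SyntheticTile:
    pixels: np.ndarray           # HxWx3 uint8
    tissue_class: str
    subtype: str | None
    true_params: TileParams


def _validate_stain_matrix(S: np.ndarray) -> None:
    if S.shape != (3, 2):
        raise DegenerateStainError("stain matrix must be 3x2")
    norms = np.linalg.norm(S, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise DegenerateStainError("stain matrix columns must be unit-norm")
    cosang = float(np.clip(S[:, 0] @ S[:, 1], -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) < 1.0:
        raise DegenerateStainError("stain vectors are collinear")


def _blob_field(size: int, n_blobs: int, radius: float, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian bumps at random centers (nuclear hematoxylin field)."""
    f = np.zeros((size, size))
    if n_blobs <= 0:
        return f
    yy, xx = np.mgrid[0:size, 0:size]
    cx = rng.uniform(0, size, n_blobs)
    cy = rng.uniform(0, size, n_blobs)
    r = np.maximum(radius * rng.normal(1.0, 0.12, n_blobs), 0.5)
    for i in range(n_blobs):
        d2 = (xx - cx[i]) ** 2 + (yy - cy[i]) ** 2
        f += amplitude * np.exp(-d2 / (2.0 * r[i] ** 2))
    return f


def _smooth_field(size: int, level: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency nonnegative field (eosin background).

    The modulation is deep enough to reach zero in patches so that the
    cohort contains nearly-pure pixels of each stain — the geometric
    assumption behind extreme-angle stain estimation.
    """
    if level <= 0:
        return np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    phase = rng.uniform(0, 2 * np.pi, 2)
    freq = rng.uniform(0.5, 1.5, 2)
    mod = np.cos(2 * np.pi * freq[0] * xx / size + phase[0]) \
        * np.cos(2 * np.pi * freq[1] * yy / size + phase[1])
    return level * np.clip(1.0 + 1.3 * mod, 0.0, None)


def render_tile(params: TileParams, size: int = 64,
                rng: np.random.Generator | None = None) -> SyntheticTile:
    """Render one tile through the Beer–Lambert model.

    ``pixels = round(255 * exp(-S @ C))`` per pixel, plus Gaussian read
    noise, clipped to [0, 255]. All-zero concentrations therefore give a
    uniform white tile.
    """
    if size < 32:
        raise ValueError("tile size must be >= 32 pixels")
    rng = np.random.default_rng() if rng is None else rng
    S = np.asarray(params.stain_matrix, dtype=float)
    _validate_stain_matrix(S)

    area_scale = (size / 64.0) ** 2
    tc = params.tissue_class
    if tc == "white":
        conc_h = np.zeros((size, size))
        conc_e = np.zeros((size, size))
    elif tc == "marker":
        # Ink: an opaque diagonal stripe; rendered directly, not through H&E.
        img = np.full((size, size, 3), 252.0)
        yy, xx = np.mgrid[0:size, 0:size]
        offset = rng.uniform(-0.3, 0.3) * size
        stripe = np.abs((xx - yy) - offset) < size * 0.12
        ink = np.array([30.0, 70.0, 45.0])  # dark green marker
        img[stripe] = ink
        img += rng.normal(0, params.noise_sd, img.shape)
        pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
        return SyntheticTile(pixels, tc, params.subtype, params)
    else:
        n_blobs = rng.poisson(params.blob_density * area_scale)
        conc_h = _blob_field(size, n_blobs, params.blob_radius,
                             params.blob_amplitude, rng)
        conc_e = _smooth_field(size, params.eosin_level, rng)

    C = np.stack([conc_h, conc_e]) * params.concentration_scale  # (2, H, W)
    od = np.tensordot(S, C, axes=1)                              # (3, H, W)
    img = 255.0 * np.exp(-od)
    img = np.moveaxis(img, 0, -1)
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticTile(pixels, tc, params.subtype, params)


def _tile_params(tissue_class: str, subtype: str | None, class_index: int | None,
                 spec: CohortSpec) -> TileParams:
    """Generating parameters for a tile of the given tissue class.

    Tumor tiles carry the planted subtype signal; every other tissue class
    is subtype-agnostic by construction.
    """
    s = spec.signal_strength
    base_density, base_radius = 32.0, 2.5
    common = dict(stain_matrix=np.asarray(spec.stain_matrix, dtype=float),
                  noise_sd=spec.noise_sd)
    if tissue_class == "tumor":
        off = _CLASS_OFFSETS[class_index]
        return TileParams(
            tissue_class, subtype,
            blob_density=base_density * (1.0 + _DENSITY_GAIN * s * off),
            blob_radius=base_radius * (1.0 + _RADIUS_GAIN * s * off),
            **common,
        )
    if tissue_class == "stroma":
        return TileParams(tissue_class, None, blob_density=2.0,
                          blob_radius=2.0, eosin_level=0.45, **common)
    if tissue_class == "epithelium":
        return TileParams(tissue_class, None, blob_density=18.0,
                          blob_radius=3.2, eosin_level=0.30, **common)
    if tissue_class == "fold":
        return TileParams(tissue_class, None, blob_density=base_density,
                          blob_radius=base_radius, eosin_level=0.35,
                          concentration_scale=2.5, **common)
    if tissue_class in ("white", "marker"):
        return TileParams(tissue_class, None, blob_density=0.0,
                          blob_radius=1.0, eosin_level=0.0, **common)
    raise ValueError(f"unknown tissue class {tissue_class!r}")


MANIFEST_COLUMNS = ["patient_id", "wsi_id", "tile_id", "x", "y",
                    "tissue_class", "subtype", "path"]


def generate_cohort(spec: CohortSpec, out_dir: str | Path,
                    write_tiles: bool = True) -> pd.DataFrame:
    """Generate a cohort of tiles on disk plus its manifest.

    One manifest row per tile. Tiles are written as uncompressed 8-bit RGB
    TIFF under ``out_dir/<wsi_id>/``; the manifest is also written to
    ``out_dir/manifest.csv``. A splittable RNG hierarchy (cohort -> WSI ->
    tile) makes any subset reproducible from ``spec.seed`` alone.
    """
    if spec.n_patients_per_class <= 0 or spec.wsis_per_patient <= 0 \
            or spec.tiles_per_wsi <= 0:
        raise EmptyCohortError("cohort must contain at least one patient, "
                               "WSI and tile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    non_tumor = list(_NON_TUMOR_MIX)
    non_tumor_p = np.array([_NON_TUMOR_MIX[t] for t in non_tumor])

    # Grid side for virtual tile coordinates within a WSI.
    grid_w = int(np.ceil(np.sqrt(spec.tiles_per_wsi)))

    rows = []
    wsi_index = 0
    for ci, cls in enumerate(spec.class_names):
        for pi in range(spec.n_patients_per_class):
            patient_id = f"{cls}_P{pi:03d}"
            for wi in range(spec.wsis_per_patient):
                wsi_id = f"{patient_id}_W{wi}"
                wsi_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=spec.seed,
                                           spawn_key=(wsi_index,)))
                wsi_dir = out_dir / wsi_id
                if write_tiles:
                    wsi_dir.mkdir(exist_ok=True)
                for ti in range(spec.tiles_per_wsi):
                    is_tumor = wsi_rng.random() < spec.tumor_fraction
                    if is_tumor:
                        tissue = "tumor"
                    else:
                        tissue = non_tumor[
                            wsi_rng.choice(len(non_tumor), p=non_tumor_p)]
                    subtype = cls if tissue == "tumor" else None
                    params = _tile_params(tissue, subtype,
                                          ci if tissue == "tumor" else None,
                                          spec)
                    tile = render_tile(params, size=spec.tile_size, rng=wsi_rng)
                    tile_id = f"{wsi_id}_T{ti:04d}"
                    x = (ti % grid_w) * spec.tile_size
                    y = (ti // grid_w) * spec.tile_size
                    path = wsi_dir / f"{tile_id}.tiff"
                    if write_tiles:
                        tifffile.imwrite(path, tile.pixels, compression=None)
                    rows.append((patient_id, wsi_id, tile_id, x, y,
                                 tissue, subtype if subtype else "",
                                 str(path)))
                wsi_index += 1

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_tile(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def load_tiles(manifest: pd.DataFrame) -> np.ndarray:
    """Stack the tiles of a manifest into an (N, H, W, 3) uint8 array."""
    return np.stack([tifffile.imread(p) for p in manifest["path"]])
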