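"""Tile tessellation, background/blur QC and Macenko stain normalisation.

Slides are tessellated into non-overlapping tiles of fixed physical edge
length (default 256 um) resampled to 224x224 px, i.e. an effective resolution
of ~1.14 um/px.  Tiles are screened with a Canny-edge criterion (blank or
blurred tiles carry few edges; background tiles are bright) and optionally
colour-normalised with the Macenko method: stain vectors are estimated from
the optical-density point cloud of each slide and tile colours are re-rendered
under a fixed reference stain basis so staining differences between cohorts do
not leak into the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import resize


@dataclass
class QCMetrics:
    """Per-tile quality metrics and the keep/reject decision."""

    edge_fraction: float
    mean_brightness: float
    keep: bool


@dataclass(frozen=True)
class QCThresholds:
    """Canny-based QC rule: keep iff ``edge_fraction >= edge_min`` and
    ``mean_brightness <= bright_max``.  Hysteresis thresholds operate on the
    0-255 grayscale image."""

    edge_min: float = 0.02
    bright_max: float = 240.0
    canny_low: float = 10.0
    canny_high: float = 30.0
    canny_sigma: float = 1.0


@dataclass
class TileRecord:
    """One extracted tile with its grid position and provenance."""

    slide_id: str
    grid_xy: tuple[int, int]  # (column, row), 0-based
    origin_px: tuple[int, int]  # top-left corner in level-0 pixels
    pixels: np.ndarray  # (out_px, out_px, 3) uint8
    qc: QCMetrics | None = None
    normalised: bool = False

    def __post_init__(self) -> None:
        if min(self.origin_px) < 0:
            raise ValueError("origin_px must be non-negative")
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError("pixels must be a square RGB array")


class StainEstimationError(RuntimeError):
    """Raised when a slide has too little tissue, or a rank-deficient OD
    cloud, for stain vectors to be estimated; callers should skip
    normalisation for that slide."""


@dataclass
class StainModel:
    """Estimated stain basis: 3x2 matrix of unit optical-density columns
    (column 0 hematoxylin-like, column 1 eosin-like) and the 99th-percentile
    concentration per stain used for intensity matching."""

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.stain_matrix, dtype=float)
        if S.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        if not np.allclose(np.linalg.norm(S, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit norm")
        cosang = float(S[:, 0] @ S[:, 1])
        if not (0.0 < cosang < 1.0 - 1e-9):
            raise ValueError("stain column angle must be strictly between 0 and 90 deg")
        self.stain_matrix = S
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.max_concentrations.shape != (2,) or np.any(self.max_concentrations <= 0):
            raise ValueError("max_concentrations must be a positive pair")


# Fixed built-in reference basis (standard H&E optical-density vectors) so
# normalisation is reproducible without estimating a target from data; any
# StainModel may be passed instead.
_REF = np.array([[0.650, 0.072], [0.704, 0.990], [0.286, 0.105]])
DEFAULT_REFERENCE = StainModel(
    stain_matrix=_REF / np.linalg.norm(_REF, axis=0, keepdims=True),
    max_concentrations=np.array([1.5, 1.0]),
)


# ---------------------------------------------------------------------------


def tessellate(
    image: np.ndarray,
    mpp: float,
    tile_um: float = 256.0,
    out_px: int = 224,
    slide_id: str = "slide",
) -> list[TileRecord]:
    """Cut ``image`` into a non-overlapping grid of tiles of physical edge
    ``tile_um`` microns, each resampled to ``out_px`` square.

    The source window side is ``round(tile_um / mpp)`` pixels; partial tiles at
    the right/bottom edges are dropped, so the tile count is exactly
    ``floor(W/side) * floor(H/side)``.  Grid coordinates are 0-based
    (column, row) with origin at the top-left; windows are half-open.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    H, W = image.shape[:2]
    side = int(round(tile_um / mpp))
    n_cols, n_rows = W // side, H // side
    if n_cols == 0 or n_rows == 0:
        warnings.warn(
            f"image {W}x{H} smaller than one {side}px tile; no tiles produced",
            stacklevel=2,
        )
        return []
    tiles = []
    for row in range(n_rows):
        for col in range(n_cols):
            y0, x0 = row * side, col * side
            window = image[y0 : y0 + side, x0 : x0 + side, :3]
            if side != out_px:
                window = resize(
                    window.astype(float),
                    (out_px, out_px, 3),
                    order=1,
                    anti_aliasing=side > out_px,
                    preserve_range=True,
                )
            pixels = np.clip(np.round(window), 0, 255).astype(np.uint8)
            tiles.append(
                TileRecord(
                    slide_id=slide_id,
                    grid_xy=(col, row),
                    origin_px=(x0, y0),
                    pixels=pixels,
                )
            )
    return tiles


def qc_tile(tile: TileRecord, thresholds: QCThresholds = QCThresholds()) -> QCMetrics:
    """Compute Canny edge fraction and mean brightness; decide keep/reject.

    Blank background tiles have near-zero edge fraction and high brightness;
    blurred tiles lose edges relative to their sharp originals.  Metrics are
    populated even when the tile is rejected.
    """
    gray = rgb2gray(tile.pixels) * 255.0
    edges = canny(
        gray,
        sigma=thresholds.canny_sigma,
        low_threshold=thresholds.canny_low,
        high_threshold=thresholds.canny_high,
    )
    edge_fraction = float(edges.mean())
    brightness = float(gray.mean())
    keep = edge_fraction >= thresholds.edge_min and brightness <= thresholds.bright_max
    metrics = QCMetrics(edge_fraction=edge_fraction, mean_brightness=brightness, keep=keep)
    tile.qc = metrics
    return metrics


# ---------------------------------------------------------------------------
# Macenko


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Optical density per channel: ``-log10((I + 1) / 255)``."""
    return -np.log10((np.asarray(pixels, dtype=float) + 1.0) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped to [0, 255] uint8."""
    return np.clip(np.round(255.0 * np.power(10.0, -od) - 1.0), 0, 255).astype(np.uint8)


def estimate_stain_matrix(
    pixels: np.ndarray,
    beta: float = 0.15,
    alpha: float = 1.0,
    min_pixels: int = 100,
) -> StainModel:
    """Estimate the two-stain optical-density basis of an H&E image (Macenko).

    Pixels with any-channel OD below ``beta`` (background/near-white) are
    discarded; the top-2 eigenvectors of the OD covariance define the stain
    plane; the extreme ``alpha``-th / ``(100 - alpha)``-th percentile angles
    within that plane give the two stain directions.  Columns are sign-fixed
    non-negative and unit-normalised; the column with the larger red-channel
    OD component is assigned to hematoxylin (ties broken by larger green
    component).  ``max_concentrations`` is the 99th percentile of the
    least-squares concentrations per stain.

    Raises :class:`StainEstimationError` for images with too few tissue pixels
    or a rank-deficient (effectively single-stain) OD cloud.
    """
    od = rgb_to_od(pixels).reshape(-1, 3)
    tissue = od[np.all(od >= beta, axis=1)]
    if tissue.shape[0] < min_pixels:
        raise StainEstimationError(
            f"stain estimation failed: only {tissue.shape[0]} pixels above "
            f"OD {beta} (need >= {min_pixels})"
        )
    cov = np.cov(tissue.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # quantisation noise alone gives a second eigenvalue ~1e-4 of the first;
    # genuine two-stain clouds sit orders of magnitude above that
    if evals[1] < 1e-3 * max(evals[0], 1e-30) or evals[1] <= 0:
        raise StainEstimationError(
            "stain estimation failed: rank-deficient OD cloud (single stain?)"
        )
    plane = evecs[:, :2]  # columns span the stain plane
    # lexicographic sign fix for determinism of the plane basis
    for j in range(2):
        lead = plane[np.argmax(np.abs(plane[:, j])), j]
        if lead < 0:
            plane[:, j] = -plane[:, j]
    proj = tissue @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    v = np.stack(
        [plane @ [np.cos(lo), np.sin(lo)], plane @ [np.cos(hi), np.sin(hi)]], axis=1
    )
    # sign-fix each stain vector into the non-negative OD orthant
    for j in range(2):
        if v[:, j].sum() < 0:
            v[:, j] = -v[:, j]
    v = np.clip(v, 0.0, None)
    norms = np.linalg.norm(v, axis=0)
    if np.any(norms < 1e-12):
        raise StainEstimationError("stain estimation failed: degenerate stain vector")
    v = v / norms
    # hematoxylin = larger red OD component; tie-break on green
    key = v[0] + 1e-9 * v[1]
    h_idx = int(np.argmax(key))
    S = v[:, [h_idx, 1 - h_idx]]
    if float(S[:, 0] @ S[:, 1]) >= 1.0 - 1e-9:
        raise StainEstimationError("stain estimation failed: collinear stain vectors")
    conc, *_ = np.linalg.lstsq(S, tissue.T, rcond=None)
    max_c = np.percentile(conc, 99.0, axis=1)
    if np.any(max_c <= 0):
        raise StainEstimationError("stain estimation failed: non-positive concentrations")
    return StainModel(stain_matrix=S, max_concentrations=max_c)


def normalise_pixels(
    pixels: np.ndarray, source: StainModel, reference: StainModel = DEFAULT_REFERENCE
) -> np.ndarray:
    """Re-render ``pixels`` under the reference stain basis (Macenko).

    Concentrations under the source basis are computed by least squares,
    rescaled per stain by ``reference.max_concentrations /
    source.max_concentrations``, and pushed back through the reference basis
    via Beer-Lambert.  Output is clipped to [0, 255].
    """
    shape = np.asarray(pixels).shape
    od = rgb_to_od(pixels).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(source.stain_matrix, od.T, rcond=None)
    scale = reference.max_concentrations / source.max_concentrations
    conc = conc * scale[:, None]
    od_new = (reference.stain_matrix @ conc).T
    return od_to_rgb(od_new).reshape(shape)


def macenko_normalise(
    tile: TileRecord, source: StainModel, reference: StainModel = DEFAULT_REFERENCE
) -> TileRecord:
    """Return a colour-normalised copy of ``tile`` (``normalised`` flag set)."""
    out = normalise_pixels(tile.pixels, source, reference)
    return replace(tile, pixels=out, normalised=True, qc=tile.qc)


# ---------------------------------------------------------------------------
# directory-level driver


def preprocess_slide(
    image: np.ndarray,
    mpp: float,
    slide_id: str = "slide",
    tile_um: float = 256.0,
    out_px: int = 224,
    thresholds: QCThresholds = QCThresholds(),
    normalise: bool = True,
    reference: StainModel = DEFAULT_REFERENCE,
) -> tuple[list[TileRecord], StainModel | None]:
    """Tessellate + QC + (optionally) Macenko-normalise one slide image.

    Stain vectors are estimated once per slide from the pooled pixels of
    QC-kept tiles and applied to all of that slide's tiles; if estimation
    fails the tiles pass through un-normalised (flag unset) with a warning.
    Returns (all tiles with QC populated, the slide StainModel or None).
    """
    tiles = tessellate(image, mpp, tile_um=tile_um, out_px=out_px, slide_id=slide_id)
    for t in tiles:
        qc_tile(t, thresholds)
    stain: StainModel | None = None
    if normalise:
        kept = [t for t in tiles if t.qc is not None and t.qc.keep]
        if kept:
            sample = np.concatenate([t.pixels.reshape(-1, 3) for t in kept])
            try:
                stain = estimate_stain_matrix(sample)
            except StainEstimationError as exc:
                warnings.warn(f"{slide_id}: {exc}; tiles left un-normalised", stacklevel=2)
        if stain is not None:
            tiles = [
                macenko_normalise(t, stain, reference) if (t.qc and t.qc.keep) else t
                for t in tiles
            ]
    return tiles, stain


def write_tiles(tiles: list[TileRecord], out_dir: str | Path) -> Path:
    """Write tiles as PNGs in per-slide directories plus a ``tiles.csv`` manifest."""
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tiles:
        sdir = out_dir / t.slide_id
        sdir.mkdir(exist_ok=True)
        name = f"tile_x{t.grid_xy[0]:03d}_y{t.grid_xy[1]:03d}.png"
        if t.qc is None or t.qc.keep:
            Image.fromarray(t.pixels).save(sdir / name)
        rows.append(
            {
                "slide_id": t.slide_id,
                "x": t.grid_xy[0],
                "y": t.grid_xy[1],
                "origin_x": t.origin_px[0],
                "origin_y": t.origin_px[1],
                "keep": bool(t.qc.keep) if t.qc else True,
                "edge_fraction": t.qc.edge_fraction if t.qc else np.nan,
                "brightness": t.qc.mean_brightness if t.qc else np.nan,
                "normalised": t.normalised,
                "path": str(Path(t.slide_id) / name),
            }
        )
    manifest = out_dir / "tiles.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
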