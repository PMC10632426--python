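"""Attention and prediction heatmaps, overlays, and top-attention tiles.

Two spatial layers are produced per slide from a trained model:

* the **attention layer** holds each window's pre-softmax attention logit
  ``w^T tanh(V h_k)`` (softmax weights depend on bag size, so the raw logit is
  the cross-slide-comparable quantity; layers are min-max normalised within a
  cohort before rendering);
* the **prediction layer** holds each window's positive-class probability
  obtained by applying the classifier head to that window's embedding alone
  (a bag of one), i.e. the probability of each constituent region being
  classified positive or negative.

Rendering follows fixed colour conventions: purple (low) to gold (high) for
attention, blue (negative) to red (positive) for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from matplotlib import pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .features import FeatureBag
from .model import AttMILParams, attention_logits, classify, embed

CMAP_ATTENTION = LinearSegmentedColormap.from_list(
    "purple_gold", ["#3b0a70", "#8a2be2", "#ffd700"]
)
CMAP_PREDICTION = LinearSegmentedColormap.from_list(
    "blue_red", ["#1f4ecc", "#f5f5f5", "#cc1f1f"]
)


@dataclass
class HeatmapLayer:
    """Spatial grid of attention or prediction scores for one slide."""

    kind: Literal["attention", "prediction"]
    grid: np.ndarray  # (rows, cols); NaN where no window was scored
    stride_px: int = 32
    window_px: int = 224
    normalisation: Literal["none", "cohort_minmax"] = "none"
    colormap: Literal["purple_gold", "blue_red"] = "purple_gold"

    @property
    def cmap(self):
        return CMAP_ATTENTION if self.colormap == "purple_gold" else CMAP_PREDICTION


def score_map(
    bag: FeatureBag,
    params: AttMILParams,
    stride_px: int = 32,
    window_px: int = 224,
) -> tuple[HeatmapLayer, HeatmapLayer]:
    """Attention and prediction layers for one slide's window set.

    ``bag`` holds the slide's window features with integer grid coordinates;
    attention logits come from a single forward pass over the whole window
    set, prediction probabilities from scoring each window's embedding as a
    bag of one (evaluation mode).  Grid cells without a window are NaN.
    """
    h = embed(bag.features, params)
    logits = attention_logits(h, params)
    probs = classify(h, params, training=False)[:, 1]
    xs = np.array([c[1] for c in bag.tile_coords], dtype=int)
    ys = np.array([c[2] for c in bag.tile_coords], dtype=int)
    rows, cols = ys.max() + 1, xs.max() + 1
    att = np.full((rows, cols), np.nan)
    pred = np.full((rows, cols), np.nan)
    att[ys, xs] = logits
    pred[ys, xs] = probs
    return (
        HeatmapLayer("attention", att, stride_px, window_px, colormap="purple_gold"),
        HeatmapLayer("prediction", pred, stride_px, window_px, colormap="blue_red"),
    )


def cohort_minmax(layers: Sequence[HeatmapLayer]) -> tuple[float, float]:
    """Cohort-level extremes over all layers of one kind (NaN-aware)."""
    vals = np.concatenate([l.grid.ravel() for l in layers])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values in cohort layers")
    return float(vals.min()), float(vals.max())


def normalise_scores(
    layer: HeatmapLayer, cohort_stats: tuple[float, float]
) -> HeatmapLayer:
    """Min-max scale a layer to [0, 1] using cohort-level extremes.

    Idempotent: re-normalising an already-normalised layer (whose cohort
    extremes are then 0 and 1) leaves it unchanged.  A degenerate cohort
    (min == max) maps everything to 0.5 with a warning.
    """
    lo, hi = cohort_stats
    grid = layer.grid.astype(float)
    if hi <= lo:
        import warnings

        warnings.warn("degenerate cohort statistics (min == max); flat layer", stacklevel=2)
        out = np.where(np.isfinite(grid), 0.5, np.nan)
    else:
        out = np.clip((grid - lo) / (hi - lo), 0.0, 1.0)
    return replace(layer, grid=out, normalisation="cohort_minmax")


def render_overlay(
    layer: HeatmapLayer,
    slide_image: np.ndarray,
    alpha: float = 0.5,
) -> np.ndarray:
    """Blend a heatmap layer over a slide thumbnail; returns an RGB uint8 array.

    The layer is nearest-neighbour upsampled to the thumbnail size (with a
    warning if the aspect does not match exactly); NaN cells show the
    thumbnail unblended.
    """
    img = np.asarray(slide_image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    H, W = img.shape[:2]
    gr, gc = layer.grid.shape
    exp_h, exp_w = gr * layer.stride_px, gc * layer.stride_px
    if (exp_h, exp_w) != (H, W):
        import warnings

        warnings.warn(
            f"layer geometry {exp_w}x{exp_h} != thumbnail {W}x{H}; rescaling layer",
            stacklevel=2,
        )
    ry = np.minimum((np.arange(H) * gr) // H, gr - 1)
    rx = np.minimum((np.arange(W) * gc) // W, gc - 1)
    up = layer.grid[np.ix_(ry, rx)]
    finite = np.isfinite(up)
    vals = np.where(finite, up, 0.0)
    colours = (layer.cmap(np.clip(vals, 0.0, 1.0))[..., :3] * 255).astype(float)
    out = img.astype(float)
    mask = finite[..., None]
    out = np.where(mask, (1 - alpha) * out + alpha * colours, out)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def save_overlay(
    layer: HeatmapLayer,
    slide_image: np.ndarray,
    path: str | Path,
    alpha: float = 0.5,
    title: str | None = None,
) -> Path:
    """Write an overlay PNG with a colour-scale legend."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    overlay = render_overlay(layer, slide_image, alpha=alpha)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(overlay)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    sm = plt.cm.ScalarMappable(cmap=layer.cmap)
    sm.set_array(np.array([0.0, 1.0]))
    label = ("attention (low → high)" if layer.kind == "attention"
             else "prediction (negative → positive)")
    fig.colorbar(sm, ax=ax, fraction=0.04, label=label)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def top_tiles(
    bag: FeatureBag,
    attention: np.ndarray,
    n: int = 10,
    tiles: Sequence[np.ndarray] | None = None,
) -> "pd.DataFrame":
    """Rank tiles by attention and return the top ``n`` with coordinates.

    Ties are broken deterministically by (slide_id, x, y) lexicographic order.
    If ``n`` exceeds the bag size all tiles are returned with a warning.  When
    tile images are supplied a contact sheet can be built with
    :func:`contact_sheet`.
    """
    import pandas as pd

    attention = np.asarray(attention, dtype=float)
    if attention.shape[0] != bag.n_tiles:
        raise ValueError("attention not aligned with bag tiles")
    if n > bag.n_tiles:
        import warnings

        warnings.warn(f"requested {n} tiles but bag has {bag.n_tiles}; returning all",
                      stacklevel=2)
        n = bag.n_tiles
    table = pd.DataFrame(
        {
            "slide_id": [c[0] for c in bag.tile_coords],
            "x": [c[1] for c in bag.tile_coords],
            "y": [c[2] for c in bag.tile_coords],
            "attention": attention,
            "tile_index": np.arange(bag.n_tiles),
        }
    )
    table = table.sort_values(
        ["attention", "slide_id", "x", "y"], ascending=[False, True, True, True]
    ).head(n)
    return table.reset_index(drop=True)


def contact_sheet(
    tiles: Sequence[np.ndarray], scores: Sequence[float], cols: int = 5
) -> np.ndarray:
    """Assemble tile images into a row-major contact-sheet RGB array."""
    if not len(tiles):
        raise ValueError("no tiles to collate")
    px = tiles[0].shape[0]
    n = len(tiles)
    rows = int(np.ceil(n / cols))
    sheet = np.full((rows * px, min(n, cols) * px, 3), 255, dtype=np.uint8)
    for i, t in enumerate(tiles):
        r, c = divmod(i, cols)
        sheet[r * px : (r + 1) * px, c * px : (c + 1) * px] = t
    return sheet
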