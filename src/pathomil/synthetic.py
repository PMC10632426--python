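"""Synthetic cohorts with known ground truth.

Two layers of synthesis:

* **Feature-level bags** -- patient bags of tile feature vectors with a
  controlled witness rate (only a fraction of tiles in a positive bag carry
  the label signal), class prevalence imbalance, and optionally two
  correlated binary targets.  These exercise the MIL head, training loop and
  evaluation without any imaging.
* **H&E-like tiles** -- RGB tiles rendered by Beer-Lambert stain mixing from
  a known stain-vector matrix, plus artifact/background tiles.  These
  exercise tessellation, Canny QC and Macenko stain estimation against a
  known answer.

A "shifted cohort" generator produces a deployment cohort whose
tile-signal-to-label coupling is weakened relative to the source cohort,
emulating deployment of a model onto a population where the morphology/label
relationship differs from the training population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .features import FeatureBag

# Default per-target prevalences mirror hormone-receptor positivity rates in
# female breast cancer cohorts: ~75% ER-positive, ~65% PR-positive.
DEFAULT_PREVALENCES: dict[str, float] = {"ER": 0.75, "PR": 0.65}

# Standard H&E optical-density stain vectors (hematoxylin, eosin), unit columns.
_HE_OD = np.array([[0.650, 0.072], [0.704, 0.990], [0.286, 0.105]])
DEFAULT_STAIN_MATRIX = _HE_OD / np.linalg.norm(_HE_OD, axis=0, keepdims=True)


def signal_directions(dim: int, n_targets: int = 2) -> np.ndarray:
    """Fixed orthonormal feature-space directions carrying each target's signal.

    Deterministic functions of the dimension only, so source and deployment
    cohorts generated with different seeds share the same signal geometry.
    """
    if dim < 2:
        raise ValueError("feature_dim must be >= 2")
    base = np.zeros((n_targets, dim))
    base[0] = 1.0
    if n_targets > 1:
        base[1] = [(-1.0) ** i for i in range(dim)]
    # Gram-Schmidt, robust to odd dims where the raw vectors are not orthogonal
    for i in range(n_targets):
        for j in range(i):
            base[i] -= (base[i] @ base[j]) * base[j]
        base[i] /= np.linalg.norm(base[i])
    return base


@dataclass(frozen=True)
class BagSpec:
    """Parameters of a feature-level MIL cohort.

    ``prevalence`` may be a single fraction (one target, named ``ER``) or a
    mapping target -> fraction.  ``witness_rate`` is the per-tile probability
    that a tile in a positive bag carries the signal; every positive bag is
    guaranteed at least one signal tile.  Signal tiles are noise tiles shifted
    by ``effect_size`` along a fixed unit direction per target.
    """

    n_patients: int
    tiles_per_patient_range: tuple[int, int] = (100, 300)
    feature_dim: int = 64
    witness_rate: float = 0.1
    effect_size: float = 2.0
    prevalence: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    label_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tiles_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("tiles_per_patient_range must satisfy 1 <= lo <= hi")
        if not (0.0 < self.witness_rate <= 1.0):
            raise ValueError("witness_rate must be in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        for p in self.prevalences.values():
            if not (0.0 < p < 1.0):
                raise ValueError("prevalence must be in (0, 1)")
        if not (-1.0 <= self.label_correlation <= 1.0):
            raise ValueError("label_correlation must be in [-1, 1]")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")

    @property
    def prevalences(self) -> dict[str, float]:
        if isinstance(self.prevalence, dict):
            return dict(self.prevalence)
        return {"ER": float(self.prevalence)}

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(self.prevalences)


@dataclass(frozen=True)
class SyntheticTileSpec:
    """Parameters of one rendered H&E-like tile."""

    tile_px: int = 224
    stain_matrix_true: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAIN_MATRIX.copy()
    )
    background_intensity: int = 245
    nuclei_density: float = 30.0
    is_signal: bool = False
    is_artifact: bool = False
    artifact_kind: Literal["background", "blur"] = "background"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_px < 32:
            raise ValueError("tile_px must be >= 32")
        S = np.asarray(self.stain_matrix_true, dtype=float)
        if S.shape != (3, 2) or np.any(S < -1e-12):
            raise ValueError("stain_matrix_true must be a non-negative 3x2 matrix")
        if not np.allclose(np.linalg.norm(S, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit norm")
        if not (0 <= self.background_intensity <= 255):
            raise ValueError("background_intensity must be in [0, 255]")


@dataclass(frozen=True)
class ShiftSpec:
    """How the deployment cohort differs from the source cohort.

    ``label_decoupling`` weakens the coupling between tile signal and label:
    with decoupling fraction ``f``, a tile is a signal tile with probability
    ``witness_rate * ((1 - f) * label + f * prevalence)``, so at ``f = 0`` the
    cohort matches the source design and at ``f = 1`` signal tiles occur at the
    same base rate in both classes, making labels independent of the tiles.
    The marginal signal-tile fraction is preserved in expectation, so the two
    cohorts share marginal feature statistics.  ``feature_shift`` adds a fixed
    offset vector to every tile.
    """

    mode: Literal["label_decoupling", "feature_shift", "both"] = "label_decoupling"
    decoupling_fraction: float = 0.7
    shift_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.decoupling_fraction <= 1.0):
            raise ValueError("decoupling_fraction must be in [0, 1]")


class CohortPair(NamedTuple):
    source: list[FeatureBag]
    shifted: list[FeatureBag]
    #: whether, by construction, a source-trained model is expected to lose
    #: discrimination on the shifted cohort
    expect_auroc_drop: bool


# ---------------------------------------------------------------------------
# correlated binary labels via a Gaussian copula


def _latent_correlation(p1: float, p2: float, rho: float) -> float:
    """Latent normal correlation reproducing a target point-biserial
    correlation ``rho`` between two Bernoulli(p1), Bernoulli(p2) variables."""
    if abs(rho) < 1e-12:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def gap(r: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t1, t2], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]
        )
        return (p11 - p1 * p2) / denom - rho

    lo, hi = (-0.999, 0.0) if rho < 0 else (0.0, 0.999)
    try:
        return float(optimize.brentq(gap, lo, hi, xtol=1e-4))
    except ValueError:
        # requested correlation unattainable at these margins; saturate
        return hi if rho > 0 else lo


def draw_labels(
    rng: np.random.Generator,
    n: int,
    prevalences: dict[str, float],
    label_correlation: float = 0.0,
) -> dict[str, np.ndarray]:
    """Draw (optionally correlated) binary labels for each target."""
    targets = list(prevalences)
    if len(targets) == 1 or abs(label_correlation) < 1e-12:
        return {
            t: (rng.random(n) < prevalences[t]).astype(int) for t in targets
        }
    if len(targets) != 2:
        raise ValueError("label_correlation is only supported for two targets")
    p1, p2 = (prevalences[t] for t in targets)
    r = _latent_correlation(p1, p2, label_correlation)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]], size=n)
    return {
        targets[0]: (z[:, 0] < stats.norm.ppf(p1)).astype(int),
        targets[1]: (z[:, 1] < stats.norm.ppf(p2)).astype(int),
    }


def allred_labels(
    rng: np.random.Generator, n: int, prevalence: float
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic IHC scores on the 0-8 Allred-style scale, dichotomised at >= 3.

    The score distribution is calibrated so that ``P(score >= 3) = prevalence``;
    only the binary label is used downstream.
    """
    positive = rng.random(n) < prevalence
    scores = np.where(positive, rng.integers(3, 9, size=n), rng.integers(0, 3, size=n))
    return scores, (scores >= 3).astype(int)


# ---------------------------------------------------------------------------
# feature-level bags


def _bag_coords(pid: str, n_tiles: int, cols: int = 8) -> list[tuple[str, int, int]]:
    return [(f"{pid}_s0", i % cols, i // cols) for i in range(n_tiles)]


def generate_feature_bags(spec: BagSpec) -> list[FeatureBag]:
    """Generate a cohort of feature bags with ground-truth per-tile signal flags.

    Noise tiles are standard multivariate normal in feature space; signal
    tiles add ``effect_size`` along a fixed unit direction per target.  A
    positive bag always contains at least one signal tile for that target;
    negative bags contain none.  Raises if any target degenerates to a single
    class, rather than silently producing an unlearnable cohort.
    """
    rng = np.random.default_rng(spec.seed)
    prevalences = spec.prevalences
    labels = draw_labels(rng, spec.n_patients, prevalences, spec.label_correlation)
    for t, y in labels.items():
        if y.min() == y.max():
            raise ValueError(
                f"degenerate cohort: target {t!r} has a single class at "
                f"n_patients={spec.n_patients} (prevalence {prevalences[t]}); "
                "increase n_patients or adjust prevalence"
            )
    directions = signal_directions(spec.feature_dim, len(prevalences))
    lo, hi = spec.tiles_per_patient_range
    bags = []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        n_tiles = int(rng.integers(lo, hi + 1))
        feats = rng.standard_normal((n_tiles, spec.feature_dim))
        truth = {}
        for j, t in enumerate(labels):
            flags = np.zeros(n_tiles, dtype=bool)
            if labels[t][i] == 1:
                flags = rng.random(n_tiles) < spec.witness_rate
                if not flags.any():
                    flags[rng.integers(n_tiles)] = True
                feats[flags] += spec.effect_size * directions[j]
            truth[t] = flags
        bags.append(
            FeatureBag(
                patient_id=pid,
                slide_ids=(f"{pid}_s0",),
                features=feats,
                tile_coords=_bag_coords(pid, n_tiles),
                labels={t: int(labels[t][i]) for t in labels},
                tile_truth=truth,
            )
        )
    return bags


def generate_cohort_pair(bag_spec: BagSpec, shift: ShiftSpec) -> CohortPair:
    """Generate a source cohort and a distribution-shifted deployment cohort.

    The source cohort follows ``bag_spec`` exactly.  The shifted cohort is
    drawn with the same marginal design (prevalences, bag sizes, noise) but
    its tile-signal-to-label coupling is weakened per ``shift`` (see
    :class:`ShiftSpec`).
    """
    source = generate_feature_bags(bag_spec)
    rng = np.random.default_rng(np.random.SeedSequence([bag_spec.seed, 7919]).generate_state(1)[0])
    prevalences = bag_spec.prevalences
    labels = draw_labels(rng, bag_spec.n_patients, prevalences, bag_spec.label_correlation)
    directions = signal_directions(bag_spec.feature_dim, len(prevalences))
    f = shift.decoupling_fraction if shift.mode in ("label_decoupling", "both") else 0.0
    offset = None
    if shift.mode in ("feature_shift", "both") and shift.shift_vector is not None:
        offset = np.asarray(shift.shift_vector, dtype=float)
        if offset.shape != (bag_spec.feature_dim,):
            raise ValueError("shift_vector must have length feature_dim")
    lo, hi = bag_spec.tiles_per_patient_range
    shifted = []
    for i in range(bag_spec.n_patients):
        pid = f"Q{i:04d}"
        n_tiles = int(rng.integers(lo, hi + 1))
        feats = rng.standard_normal((n_tiles, bag_spec.feature_dim))
        truth = {}
        for j, t in enumerate(labels):
            p_signal = bag_spec.witness_rate * (
                (1.0 - f) * labels[t][i] + f * prevalences[t]
            )
            flags = rng.random(n_tiles) < p_signal
            if f == 0.0 and labels[t][i] == 1 and not flags.any():
                flags[rng.integers(n_tiles)] = True
            feats[flags] += bag_spec.effect_size * directions[j]
            truth[t] = flags
        if offset is not None:
            feats = feats + offset
        shifted.append(
            FeatureBag(
                patient_id=pid,
                slide_ids=(f"{pid}_s0",),
                features=feats,
                tile_coords=_bag_coords(pid, n_tiles),
                labels={t: int(labels[t][i]) for t in labels},
                tile_truth=truth,
            )
        )
    expect_drop = f > 0.0 or (offset is not None and np.any(offset != 0))
    return CohortPair(source=source, shifted=shifted, expect_auroc_drop=expect_drop)


# ---------------------------------------------------------------------------
# H&E-like tile rendering (Beer-Lambert)


def _nuclei_concentration(
    rng: np.random.Generator, px: int, density: float, radius: float
) -> np.ndarray:
    """Hematoxylin concentration map: sum of Gaussian nuclear blobs."""
    c = np.zeros((px, px))
    n = rng.poisson(density)
    if n == 0:
        return c
    yy, xx = np.mgrid[0:px, 0:px]
    centers = rng.uniform(0, px, size=(n, 2))
    amps = rng.uniform(0.9, 1.8, size=n)
    sigmas = rng.uniform(0.8, 1.2, size=n) * radius
    for (cy, cx), a, s in zip(centers, amps, sigmas):
        c += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    return c


def generate_he_tile(spec: SyntheticTileSpec) -> np.ndarray:
    """Render one RGB tile via Beer-Lambert transmission ``I = 255 * 10^(-S c)``.

    Tissue tiles mix two concentration fields: Gaussian nuclear blobs weighted
    to stain column 1 (hematoxylin-like) and a smooth stroma texture weighted
    to stain column 2 (eosin-like).  Signal tiles carry denser, larger nuclei
    so a downstream extractor can distinguish them.  Artifact tiles are either
    near-uniform bright background or a heavily blurred tissue render.
    Pixel-deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.tile_px
    if spec.is_artifact and spec.artifact_kind == "background":
        base = spec.background_intensity + rng.uniform(0.0, 3.0, size=(px, px, 3))
        return np.clip(np.round(base), 0, 255).astype(np.uint8)

    density = spec.nuclei_density * (4.0 if spec.is_signal else 1.0)
    radius = px / 64.0 * (1.6 if spec.is_signal else 1.0)
    c_h = _nuclei_concentration(rng, px, density, radius)
    stroma = ndimage.gaussian_filter(rng.standard_normal((px, px)), sigma=px / 16.0)
    stroma = (stroma - stroma.min()) / max(np.ptp(stroma), 1e-12)
    # deep eosin staining (OD above the Macenko tissue threshold in every
    # channel at the strong end), suppressed under nuclei
    c_e = (0.25 + 1.9 * stroma) * np.clip(1.0 - 0.9 * np.minimum(c_h, 1.0), 0.0, 1.0)
    conc = np.stack([c_h, c_e])  # (2, px, px)
    od = np.tensordot(np.asarray(spec.stain_matrix_true, float), conc, axes=([1], [0]))
    # render through the package's single OD convention (see preprocess.od_to_rgb)
    from .preprocess import od_to_rgb

    img = od_to_rgb(np.moveaxis(od, 0, -1)).astype(float)
    if spec.is_artifact and spec.artifact_kind == "blur":
        img = ndimage.gaussian_filter(img, sigma=(px / 10.0, px / 10.0, 0.0))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_tile_mosaic(
    specs: Sequence[SyntheticTileSpec],
) -> np.ndarray:
    """Tile a row-major square-ish mosaic from individually rendered tiles.

    Useful for driving tessellation and stain estimation on a single image
    built from tiles with known stain chemistry.
    """
    if not specs:
        raise ValueError("need at least one tile spec")
    px = specs[0].tile_px
    n = len(specs)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    mosaic = np.full((rows * px, cols * px, 3), 255, dtype=np.uint8)
    for i, s in enumerate(specs):
        r, c = divmod(i, cols)
        mosaic[r * px : (r + 1) * px, c * px : (c + 1) * px] = generate_he_tile(s)
    return mosaic


# ---------------------------------------------------------------------------
# on-disk image cohorts


def write_image_cohort(
    out_dir,
    n_patients: int,
    tiles_per_patient: int = 12,
    tile_px: int = 64,
    prevalence: float = 0.75,
    witness_rate: float = 0.3,
    stain_matrix: np.ndarray | None = None,
    artifact_rate: float = 0.1,
    seed: int = 0,
    target: str = "ER",
):
    """Write a small synthetic image cohort: per-slide PNG tile directories, a
    ``labels.csv`` (patient_id, slide_id, target columns with Allred-derived
    binary status) and a ``tile_truth.csv`` with per-tile signal/artifact flags.

    Returns the paths (root, labels_csv, truth_csv).
    """
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    S = DEFAULT_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix)
    scores, labels = allred_labels(rng, n_patients, prevalence)
    label_rows, truth_rows = [], []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        slide = f"{pid}_s0"
        sdir = out_dir / slide
        sdir.mkdir(exist_ok=True)
        label_rows.append(
            {"patient_id": pid, "slide_id": slide, "target": target,
             "status": int(labels[i]), "allred_score": int(scores[i])}
        )
        for j in range(tiles_per_patient):
            is_artifact = rng.random() < artifact_rate
            is_signal = bool(labels[i]) and not is_artifact and rng.random() < witness_rate
            tile = generate_he_tile(
                SyntheticTileSpec(
                    tile_px=tile_px,
                    stain_matrix_true=S,
                    is_signal=is_signal,
                    is_artifact=is_artifact,
                    nuclei_density=max(4.0, tile_px * tile_px / 600.0),
                    seed=int(rng.integers(2**31)),
                )
            )
            name = f"tile_{j:03d}.png"
            Image.fromarray(tile).save(sdir / name)
            truth_rows.append(
                {"slide_id": slide, "tile": name, "is_signal": is_signal,
                 "is_artifact": is_artifact}
            )
    import pandas as pd

    labels_csv = out_dir / "labels.csv"
    truth_csv = out_dir / "tile_truth.csv"
    pd.DataFrame(label_rows).to_csv(labels_csv, index=False)
    pd.DataFrame(truth_rows).to_csv(truth_csv, index=False)
    return out_dir, labels_csv, truth_csv
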