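"""Tile -> feature-vector contract consumed by the MIL head.

The MIL head is agnostic to where tile features come from.  Any callable
satisfying :class:`ExtractorContract` can be plugged in; the package ships a
deterministic :class:`BuiltinExtractor` (downsample + seeded random projection
+ tanh) so the full pipeline runs and is testable without a pretrained
histology encoder.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from skimage.transform import resize


@dataclass
class FeatureBag:
    """One patient's bag of tile feature vectors.

    The bag is the unit of weak supervision: only the bag (patient) carries
    labels, individual tiles do not.

    Attributes
    ----------
    patient_id
        Patient identifier.
    slide_ids
        Slides contributing tiles to this bag.
    features
        ``(n_tiles, d)`` float array; row ``k`` is tile ``k``'s feature vector.
    tile_coords
        Per-tile ``(slide_id, x, y)`` grid coordinates, aligned 1:1 with
        feature rows.
    labels
        Mapping target name -> binary status (0/1) or ``None`` when unknown.
    tile_truth
        Optional per-target ground-truth signal flags (synthetic cohorts only);
        mapping target -> boolean array of length ``n_tiles``.
    """

    patient_id: str
    slide_ids: tuple[str, ...]
    features: np.ndarray
    tile_coords: list[tuple[str, int, int]]
    labels: dict[str, int | None] = field(default_factory=dict)
    tile_truth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty (n_tiles, d) matrix")
        if len(self.tile_coords) != self.n_tiles:
            raise ValueError(
                f"tile_coords length {len(self.tile_coords)} != n_tiles {self.n_tiles}"
            )

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def permuted(self, order: np.ndarray) -> "FeatureBag":
        """Return a copy with tiles re-ordered by ``order`` (rows and coords move together)."""
        order = np.asarray(order)
        return FeatureBag(
            patient_id=self.patient_id,
            slide_ids=self.slide_ids,
            features=self.features[order],
            tile_coords=[self.tile_coords[i] for i in order],
            labels=dict(self.labels),
            tile_truth={t: m[order] for t, m in self.tile_truth.items()},
        )


@dataclass(frozen=True)
class ExtractorContract:
    """What the pipeline requires of a tile feature extractor."""

    name: str
    output_dim: int
    deterministic: bool = True


class BuiltinExtractor:
    """Deterministic lightweight tile encoder.

    Downsamples the tile to 16x16x3, flattens, applies a fixed seeded Gaussian
    random projection to ``d`` dimensions, then a tanh nonlinearity.  Not a
    learned representation -- it preserves coarse colour/texture structure,
    which is all the synthetic benchmarks need -- but it honours the same
    contract as a pretrained encoder and is bit-reproducible.
    """

    def __init__(self, d: int = 64, seed: int = 0):
        if d < 2:
            raise ValueError("output dimension must be >= 2")
        self.contract = ExtractorContract(name=f"builtin-rp{d}", output_dim=d, deterministic=True)
        rng = np.random.default_rng(seed)
        n_in = 16 * 16 * 3
        self._proj = rng.standard_normal((d, n_in)) / np.sqrt(n_in)
        self.seed = seed

    @property
    def name(self) -> str:
        return self.contract.name

    @property
    def output_dim(self) -> int:
        return self.contract.output_dim

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=float)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError("expected an RGB (H, W, 3) tile")
        small = resize(pixels / 255.0, (16, 16, 3), order=1, anti_aliasing=True,
                       preserve_range=True)
        return np.tanh(self._proj @ small.ravel())


def extract_features(
    tiles_by_patient: Mapping[str, Sequence],
    extractor: Callable[[np.ndarray], np.ndarray],
    labels: Mapping[str, Mapping[str, int | None]] | None = None,
) -> list[FeatureBag]:
    """Build one :class:`FeatureBag` per patient from QC-kept tiles.

    Parameters
    ----------
    tiles_by_patient
        Mapping patient_id -> sequence of :class:`~pathomil.preprocess.TileRecord`
        (across all of that patient's slides, in manifest order).
    extractor
        Callable tile-pixels -> feature vector.
    labels
        Optional mapping patient_id -> {target: 0/1}.

    Patients with zero kept tiles are excluded with a warning rather than
    producing empty bags.
    """
    bags: list[FeatureBag] = []
    for pid, tiles in tiles_by_patient.items():
        kept = [t for t in tiles if t.qc is None or t.qc.keep]
        if not kept:
            warnings.warn(f"patient {pid!r} has no QC-kept tiles; excluded", stacklevel=2)
            continue
        feats = np.stack([np.asarray(extractor(t.pixels)) for t in kept])
        coords = [(t.slide_id, int(t.grid_xy[0]), int(t.grid_xy[1])) for t in kept]
        slide_ids = tuple(dict.fromkeys(t.slide_id for t in kept))
        bag_labels = dict(labels[pid]) if labels is not None and pid in labels else {}
        bags.append(FeatureBag(pid, slide_ids, feats, coords, labels=bag_labels))
    return bags


# ---------------------------------------------------------------------------
# feature store: one .npz per patient + a CSV index


def save_bags(bags: Sequence[FeatureBag], out_dir: str | Path, extractor_name: str = "unknown") -> Path:
    """Write bags as per-patient ``.npz`` containers plus a ``features.csv`` index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for bag in bags:
        path = out_dir / f"{bag.patient_id}.npz"
        coords_slide = np.array([c[0] for c in bag.tile_coords])
        coords_xy = np.array([[c[1], c[2]] for c in bag.tile_coords], dtype=int)
        payload: dict[str, np.ndarray] = {
            "features": bag.features,
            "coords_slide": coords_slide,
            "coords_xy": coords_xy,
        }
        for t, m in bag.tile_truth.items():
            payload[f"truth_{t}"] = np.asarray(m, dtype=bool)
        np.savez(path, **payload)
        meta = {
            "patient_id": bag.patient_id,
            "path": path.name,
            "n_tiles": bag.n_tiles,
            "d": bag.dim,
            "extractor": extractor_name,
            "slide_ids": json.dumps(list(bag.slide_ids)),
            "labels": json.dumps({k: v for k, v in bag.labels.items()}),
        }
        rows.append(meta)
    import pandas as pd

    index = out_dir / "features.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_bags(index_csv: str | Path) -> list[FeatureBag]:
    """Load a feature store written by :func:`save_bags`."""
    import pandas as pd

    index_csv = Path(index_csv)
    table = pd.read_csv(index_csv)
    bags = []
    for _, row in table.iterrows():
        data = np.load(index_csv.parent / row["path"], allow_pickle=False)
        coords = [
            (str(s), int(xy[0]), int(xy[1]))
            for s, xy in zip(data["coords_slide"], data["coords_xy"])
        ]
        truth = {
            k.removeprefix("truth_"): data[k]
            for k in data.files
            if k.startswith("truth_")
        }
        labels = {
            k: (int(v) if v is not None else None)
            for k, v in json.loads(row["labels"]).items()
        }
        bags.append(
            FeatureBag(
                patient_id=str(row["patient_id"]),
                slide_ids=tuple(json.loads(row["slide_ids"])),
                features=data["features"],
                tile_coords=coords,
                labels=labels,
                tile_truth=truth,
            )
        )
    return bags


def tile_hash(pixels: np.ndarray) -> str:
    """Content hash of a tile, used to key feature caches."""
    return hashlib.sha1(np.ascontiguousarray(pixels).tobytes()).hexdigest()
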