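"""Synthetic labeled hyperspectral scenes with controllable separability.

Real agricultural benchmarks are contiguous fields of crops whose spectra are
smooth curves over band index, some pairs of which (e.g. two grape
cultivars) are nearly identical.  The generator emulates exactly that
structure: each class gets a smooth signature built from Gaussian bumps over
the band axis, the image is tiled into contiguous class regions (rectangular
strips or Voronoi cells), per-band white Gaussian noise is added, and a
fraction of pixels is left unlabeled as background.  "Confusable" class
pairs share a signature shifted by a small band offset, which dials their
spectral distance continuously down to zero.

Everything is a deterministic function of the :class:`SceneSpec` (including
its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsi_data import GroundTruthMap, HSICube

__all__ = ["SceneSpec", "class_signature", "generate_scene", "scene_separability"]


@dataclass
class SceneSpec:
    rows: int = 64
    columns: int = 64
    bands: int = 32
    n_classes: int = 5
    region_model: str = "rectangles"          # or "voronoi"
    noise_sd: float = 0.05
    # (base_class, confusable_class, band_offset): the second class reuses the
    # first's signature shifted by `band_offset` bands.
    confusable_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unlabeled_fraction: float = 0.1
    bump_width: float | None = None           # default bands / 8
    amplitude: float = 1.0
    secondary_amplitude: float = 0.5          # 0 => pure single-bump signatures
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.unlabeled_fraction < 1):
            raise ValueError("unlabeled_fraction must be in [0, 1)")
        if self.region_model not in ("rectangles", "voronoi"):
            raise ValueError(f"unknown region model {self.region_model!r}")
        if self.rows * self.columns < self.n_classes:
            raise ValueError("image too small to place every class")


def _bumps(spec: SceneSpec, class_id: int) -> list[tuple[float, float, float]]:
    """(center, width, amplitude) triples defining a class signature."""
    width = spec.bump_width if spec.bump_width is not None else spec.bands / 8
    # primary bumps evenly spread over the band axis, one slot per class
    c1 = spec.bands * (class_id - 0.5) / spec.n_classes
    out = [(c1, width, spec.amplitude)]
    if spec.secondary_amplitude > 0:
        out.append((min(c1 + spec.bands / 3, spec.bands - 1.0),
                    0.8 * width, spec.secondary_amplitude))
    return out


def class_signature(class_id: int, spec: SceneSpec) -> np.ndarray:
    """Smooth non-negative mean spectrum of one class (length = bands)."""
    if not (1 <= class_id <= spec.n_classes):
        raise ValueError(f"unknown class {class_id}")
    shift = 0.0
    base = class_id
    for a, b, offset in spec.confusable_pairs:
        if class_id == b:
            base, shift = a, float(offset)
            break
    band = np.arange(spec.bands, dtype=np.float64) - shift
    sig = np.zeros(spec.bands)
    for center, width, amp in _bumps(spec, base):
        sig += amp * np.exp(-0.5 * ((band - center) / width) ** 2)
    return sig


def _region_labels(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.region_model == "rectangles":
        # contiguous horizontal strips, one per class (field-like blocks)
        edges = np.linspace(0, spec.rows, spec.n_classes + 1).astype(int)
        labels = np.zeros((spec.rows, spec.columns), dtype=np.int64)
        for c in range(1, spec.n_classes + 1):
            labels[edges[c - 1]:edges[c], :] = c
        labels[labels == 0] = spec.n_classes   # rounding slack joins last strip
        return labels
    # voronoi: nearest of n_classes random sites
    sites = np.column_stack([rng.uniform(0, spec.rows, spec.n_classes),
                             rng.uniform(0, spec.columns, spec.n_classes)])
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.columns),
                         indexing="ij")
    d2 = ((rr[..., None] - sites[:, 0]) ** 2
          + (cc[..., None] - sites[:, 1]) ** 2)
    return d2.argmin(axis=2).astype(np.int64) + 1


def generate_scene(spec: SceneSpec) -> tuple[HSICube, GroundTruthMap]:
    """Realize a scene: spectra = class signature + N(0, noise_sd^2) per band."""
    rng = np.random.default_rng(spec.seed)
    regions = _region_labels(spec, rng)
    for c in range(1, spec.n_classes + 1):
        if not (regions == c).any():
            raise ValueError(f"class {c} received no pixels")

    signatures = np.stack([class_signature(c, spec)
                           for c in range(1, spec.n_classes + 1)])
    cube = signatures[regions - 1].astype(np.float64)
    if spec.noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.noise_sd, size=cube.shape)

    labels = regions.copy()
    if spec.unlabeled_fraction > 0:
        n_px = spec.rows * spec.columns
        n_bg = int(round(spec.unlabeled_fraction * n_px))
        flat = rng.permutation(n_px)[:n_bg]
        labels.flat[flat] = 0
        # keep the invariant: every class still occupies >= 1 labeled pixel
        for c in range(1, spec.n_classes + 1):
            if not (labels == c).any():
                cand = np.argwhere(regions == c)[0]
                labels[cand[0], cand[1]] = c
    return (HSICube(cube, name=f"synthetic-seed{spec.seed}"),
            GroundTruthMap(labels))


def scene_separability(cube: HSICube, gt: GroundTruthMap) -> pd.DataFrame:
    """Pairwise Euclidean distances between per-class mean spectra."""
    classes = gt.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present")
    means = []
    for c in classes:
        mask = gt.labels == c
        if not mask.any():
            raise ValueError(f"class {c} has no pixels")
        means.append(cube.values[mask].mean(axis=0))
    means = np.stack(means)
    diff = means[:, None, :] - means[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(dist, index=classes, columns=classes)
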