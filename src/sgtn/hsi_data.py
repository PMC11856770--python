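"""Hyperspectral cubes, ground-truth maps, stratified splits and patches.

A scene is a pair of co-registered arrays: a reflectance cube of shape
(rows, columns, bands) and an integer label map of the same spatial size in
which 0 marks unlabeled background and classes are 1-based.  The classifier
consumes s x s patches cut around individual pixels, each labeled by the
class of its center pixel.

Splitting is stratified per class with the floor rule

    n_train = floor(train_frac * n)
    n_val   = floor(val_frac * (n - n_train))
    n_test  = n - n_train - n_val

so subset sizes depend only on the class totals and the fractions, while the
membership of each subset is drawn uniformly at random under the seed.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import yaml

from . import envi

__all__ = [
    "HSICube", "GroundTruthMap", "DatasetSplit", "Patch",
    "load_cube", "remove_bands", "normalize_cube", "split_counts",
    "stratified_split", "extract_patch", "make_patch_set", "patch_arrays",
    "default_band_drops", "write_split_manifest", "read_split_manifest",
]


@dataclass
class HSICube:
    """A rows x columns x bands reflectance array with band bookkeeping."""

    values: np.ndarray
    name: str = ""
    dropped_bands: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("cube must be rank-3 (rows, columns, bands)")
        if min(self.values.shape) < 1:
            raise ValueError("cube dimensions must all be >= 1")
        if np.isnan(self.values).any():
            raise ValueError("cube contains NaN values")
        if len(set(self.dropped_bands)) != len(self.dropped_bands):
            raise ValueError("dropped_bands contains duplicates")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def band_count(self) -> int:
        return self.values.shape[2]


@dataclass
class GroundTruthMap:
    """Per-pixel integer class labels; 0 = unlabeled."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be rank-2")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = np.round(self.labels).astype(np.int64)
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")

    @property
    def classes(self) -> np.ndarray:
        """Sorted distinct nonzero labels."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def class_count(self) -> int:
        return len(self.classes)


@dataclass
class Patch:
    window: np.ndarray          # s x s x bands
    center: tuple[int, int]
    label: int
    s: int


@dataclass
class DatasetSplit:
    """Per-class disjoint train/validation/test pixel coordinates."""

    train: dict[int, np.ndarray]   # class -> (n, 2) array of (row, col)
    val: dict[int, np.ndarray]
    test: dict[int, np.ndarray]
    seed: int
    fractions: tuple[float, float]

    def indices(self, subset: str) -> np.ndarray:
        """All (row, col) coordinates of one subset, classes concatenated."""
        parts = [v for _, v in sorted(getattr(self, subset).items())]
        return np.concatenate(parts) if parts else np.empty((0, 2), dtype=np.int64)

    def counts(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.train):
            nt, nv, ns = len(self.train[c]), len(self.val[c]), len(self.test[c])
            rows.append((c, nt, nv, ns, nt + nv + ns))
        return pd.DataFrame(rows, columns=["class", "train", "val", "test", "total"])


# ----------------------------------------------------------------------------- I/O


def _pick_array(container: dict, rank: int) -> np.ndarray:
    """Largest numeric array of the requested rank in a MAT-style dict."""
    best = None
    for key, val in container.items():
        if key.startswith("__"):
            continue
        arr = np.asarray(val)
        if arr.ndim == rank and np.issubdtype(arr.dtype, np.number):
            if best is None or arr.size > best.size:
                best = arr
    if best is None:
        raise ValueError(f"no rank-{rank} numeric array found in container")
    return best


def _load_array(path: Path, rank: int) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".mat":
        try:
            return _pick_array(scipy.io.loadmat(path), rank)
        except NotImplementedError:      # MAT v7.3 is HDF5
            with h5py.File(path, "r") as f:
                data = {k: np.asarray(f[k]) for k in f.keys()}
            # h5py yields MATLAB arrays transposed
            return _pick_array({k: v.T for k, v in data.items()}, rank)
    if suffix == ".hdr":
        arr = envi.read_envi(path)
        return arr[:, :, 0] if rank == 2 and arr.ndim == 3 else arr
    if suffix in (".npy",):
        return np.load(path)
    raise ValueError(f"unrecognized container format: {path}")


def load_cube(path: str | os.PathLike,
              gt_path: str | os.PathLike) -> tuple[HSICube, GroundTruthMap]:
    """Load a cube and its ground truth from MAT, ENVI or .npy containers."""
    path, gt_path = Path(path), Path(gt_path)
    for p in (path, gt_path):
        if not p.exists():
            raise FileNotFoundError(p)
    values = np.asarray(_load_array(path, 3), dtype=np.float64)
    labels = _load_array(gt_path, 2)
    if values.shape[:2] != labels.shape:
        raise ValueError(
            f"spatial dimension mismatch: cube {values.shape[:2]} vs "
            f"labels {labels.shape}")
    return HSICube(values, name=path.stem), GroundTruthMap(labels)


def remove_bands(cube: HSICube, drop_indices: list[int]) -> HSICube:
    """Drop the listed band indices (e.g. water-absorption bands)."""
    drop = list(drop_indices)
    if len(set(drop)) != len(drop):
        raise ValueError("duplicate band indices in drop list")
    nb = cube.band_count
    if any(i < 0 or i >= nb for i in drop):
        raise ValueError("band index out of range")
    keep = [i for i in range(nb) if i not in set(drop)]
    return HSICube(cube.values[:, :, keep], name=cube.name,
                   dropped_bands=cube.dropped_bands + sorted(drop))


def normalize_cube(cube: HSICube) -> HSICube:
    """Rescale each band independently to [0, 1]; constant bands map to 0."""
    v = cube.values.astype(np.float64)
    lo = v.min(axis=(0, 1), keepdims=True)
    hi = v.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    return HSICube((v - lo) / span, name=cube.name,
                   dropped_bands=list(cube.dropped_bands))


def default_band_drops(dataset: str) -> list[int]:
    """Customary water/noise band drop list (0-based) for a benchmark.

    Shipped as an editable YAML config because only the retained counts are
    standardized, not the indices.
    """
    cfg = yaml.safe_load(
        resources.files("sgtn.config").joinpath("band_drops.yaml").read_text())
    key = dataset.lower()
    if key not in cfg:
        raise KeyError(f"no default drop list for {dataset!r}")
    out: list[int] = []
    for item in cfg[key]:
        if isinstance(item, str) and "-" in item:
            lo, hi = (int(x) for x in item.split("-"))
            out.extend(range(lo, hi + 1))
        else:
            out.append(int(item))
    return out


# ------------------------------------------------------------------------ splitting


def split_counts(n: int, train_frac: float, val_frac: float) -> tuple[int, int, int]:
    """Deterministic per-class subset sizes under the floor rule."""
    n_train = math.floor(train_frac * n)
    n_val = math.floor(val_frac * (n - n_train))
    return n_train, n_val, n - n_train - n_val


def stratified_split(gt: GroundTruthMap, train_frac: float, val_frac: float,
                     seed: int) -> DatasetSplit:
    """Per-class random split; counts are seed-independent by construction."""
    if not (0 < train_frac and 0 < val_frac and train_frac + val_frac < 1):
        raise ValueError("require 0 < train_frac, val_frac and their sum < 1")
    rng = np.random.default_rng(seed)
    train: dict[int, np.ndarray] = {}
    val: dict[int, np.ndarray] = {}
    test: dict[int, np.ndarray] = {}
    for c in gt.classes:
        coords = np.argwhere(gt.labels == int(c))
        n = len(coords)
        nt, nv, _ = split_counts(n, train_frac, val_frac)
        if nt == 0:
            warnings.warn(f"class {c}: train fraction yields 0 samples",
                          stacklevel=2)
        perm = rng.permutation(n)
        train[int(c)] = coords[perm[:nt]]
        val[int(c)] = coords[perm[nt:nt + nv]]
        test[int(c)] = coords[perm[nt + nv:]]
    return DatasetSplit(train, val, test, seed=seed,
                        fractions=(train_frac, val_frac))


def write_split_manifest(split: DatasetSplit, path: str | os.PathLike) -> None:
    rows = []
    for subset in ("train", "val", "test"):
        for c, coords in sorted(getattr(split, subset).items()):
            for r, col in coords:
                rows.append((c, int(r), int(col), subset))
    pd.DataFrame(rows, columns=["class", "row", "col", "subset"]).to_csv(
        path, index=False)


def read_split_manifest(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------------------- patches


def _reflect_indices(centers: np.ndarray, n: int) -> np.ndarray:
    """Mirror (reflect, edge not repeated) indices into [0, n)."""
    if n == 1:
        return np.zeros_like(centers)
    period = 2 * (n - 1)
    idx = np.mod(centers, period)
    return np.where(idx >= n, period - idx, idx)


def extract_patch(cube: HSICube, center: tuple[int, int], s: int) -> Patch:
    """Cut the s x s window around ``center``; borders mirror-reflected."""
    if s % 2 != 1 or s < 1:
        raise ValueError("patch side s must be a positive odd integer")
    rows, cols, _ = cube.shape
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"center {center} outside image {rows}x{cols}")
    half = (s - 1) // 2
    ri = _reflect_indices(np.arange(r - half, r + half + 1), rows)
    ci = _reflect_indices(np.arange(c - half, c + half + 1), cols)
    window = cube.values[np.ix_(ri, ci)]
    return Patch(window=window, center=(r, c), label=-1, s=s)


def make_patch_set(cube: HSICube, gt: GroundTruthMap,
                   indices: np.ndarray, s: int) -> list[Patch]:
    """One labeled patch per coordinate, order preserved."""
    patches = []
    for r, c in np.asarray(indices, dtype=np.int64).reshape(-1, 2):
        label = int(gt.labels[r, c])
        if label == 0:
            raise ValueError(f"pixel ({r}, {c}) is unlabeled")
        p = extract_patch(cube, (r, c), s)
        p.label = label
        patches.append(p)
    return patches


def patch_arrays(cube: HSICube, gt: GroundTruthMap | None,
                 indices: np.ndarray, s: int,
                 dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized patch extraction: (N, s, s, bands) windows + labels.

    Labels are 0 where ``gt`` is None (full-scene prediction).
    """
    if s % 2 != 1 or s < 1:
        raise ValueError("patch side s must be a positive odd integer")
    half = (s - 1) // 2
    padded = np.pad(cube.values, ((half, half), (half, half), (0, 0)),
                    mode="reflect") if half else cube.values
    idx = np.asarray(indices, dtype=np.int64).reshape(-1, 2)
    n = len(idx)
    X = np.empty((n, s, s, cube.band_count), dtype=dtype)
    for k, (r, c) in enumerate(idx):
        X[k] = padded[r:r + s, c:c + s]
    y = (gt.labels[idx[:, 0], idx[:, 1]].astype(np.int64)
         if gt is not None else np.zeros(n, dtype=np.int64))
    return X, y
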