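"""Training loop, evaluation protocol and full-scene prediction.

Reference protocol: mini-batch Adam (learning rate 0.001, batch size 64) on
the cross-entropy loss for 100 epochs; the checkpoint with the best
validation overall accuracy is the one evaluated on the test set; results
are averaged over five repeats, each of which redraws the stratified split
and reinitializes the model under its own seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsi_data import GroundTruthMap, HSICube, patch_arrays, stratified_split
from .metrics import (ConfusionMatrix, average_accuracy, confusion_matrix,
                      kappa, overall_accuracy, per_class_accuracy)
from .model import SGTN, ModelConfig, predict_label
from .nn import Tensor

__all__ = ["TrainSpec", "Adam", "cross_entropy", "train", "evaluate",
           "RepeatSummary", "repeat_experiment", "predict_map", "render_map",
           "CLASS_PALETTE"]


@dataclass
class TrainSpec:
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive")


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of 1-based integer labels against logits."""
    labels = np.asarray(labels, dtype=np.int64)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), labels - 1] = 1.0
    lse = logits.logsumexp(axis=-1)
    picked = (logits * Tensor(onehot)).sum(axis=-1, keepdims=True)
    return (lse - picked).mean()


def _forward_batched(model: SGTN, X: np.ndarray,
                     batch_size: int = 256) -> np.ndarray:
    outs = []
    for lo in range(0, len(X), batch_size):
        outs.append(model(Tensor(X[lo:lo + batch_size])).data)
    return np.concatenate(outs) if outs else np.empty((0, model.config.n_classes))


def train(model: SGTN, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray] | None,
          spec: TrainSpec) -> tuple[SGTN, pd.DataFrame]:
    """Adam on cross-entropy; returns the best-validation-OA checkpoint.

    ``train_set``/``val_set`` are (patches (N, s, s, bands), 1-based labels).
    """
    X, y = train_set
    if len(X) == 0:
        raise ValueError("empty training set")
    k = model.config.n_classes
    if ((y < 1) | (y > k)).any():
        raise ValueError("training labels out of range 1..n_classes")
    rng = np.random.default_rng(spec.seed)
    opt = Adam(model.parameters(), lr=spec.learning_rate)
    history = []
    best_oa, best_state = -1.0, None
    for epoch in range(spec.epochs):
        order = rng.permutation(len(X))
        losses = []
        for lo in range(0, len(X), spec.batch_size):
            sel = order[lo:lo + spec.batch_size]
            logits = model(Tensor(X[sel]))
            loss = cross_entropy(logits, y[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_oa = np.nan
        if val_set is not None and len(val_set[0]):
            pred = predict_label(_forward_batched(model, val_set[0]))
            val_oa = float((pred == val_set[1]).mean())
            if val_oa > best_oa:
                best_oa = val_oa
                best_state = {n: t.data.copy()
                              for n, t in model.named_parameters().items()}
        history.append({"epoch": epoch + 1,
                        "train_loss": float(np.mean(losses)),
                        "val_oa": val_oa})
    if best_state is not None:
        for name, tensor in model.named_parameters().items():
            tensor.data = best_state[name]
    return model, pd.DataFrame(history)


def evaluate(model: SGTN, test_set: tuple[np.ndarray, np.ndarray]) -> ConfusionMatrix:
    X, y = test_set
    if len(X) == 0:
        raise ValueError("empty test set")
    pred = predict_label(_forward_batched(model, X))
    return confusion_matrix(y, pred, model.config.n_classes)


@dataclass
class RepeatSummary:
    metrics: pd.DataFrame          # columns: repeat, seed, oa, aa, kappa
    per_class: pd.DataFrame        # rows: class; columns: mean, sd

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = self.metrics[metric].to_numpy()
        return float(vals.mean()), float(vals.std(ddof=0))


def run_once(cube: HSICube, gt: GroundTruthMap, config: ModelConfig,
             train_spec: TrainSpec, fractions: tuple[float, float],
             seed: int) -> tuple[SGTN, ConfusionMatrix, pd.DataFrame]:
    """One repeat: redraw split, rebuild model, train, evaluate on test."""
    split = stratified_split(gt, fractions[0], fractions[1], seed=seed)
    sets = {name: patch_arrays(cube, gt, split.indices(name), config.s)
            for name in ("train", "val", "test")}
    model = SGTN(ModelConfig(**{**config.__dict__, "seed": seed}))
    model, history = train(model, sets["train"], sets["val"],
                           TrainSpec(**{**train_spec.__dict__, "seed": seed}))
    return model, evaluate(model, sets["test"]), history


def repeat_experiment(cube: HSICube, gt: GroundTruthMap, config: ModelConfig,
                      train_spec: TrainSpec,
                      fractions: tuple[float, float] = (0.1, 0.1),
                      n_repeats: int = 5,
                      seeds: list[int] | None = None) -> RepeatSummary:
    """Average OA/AA/Kappa over repeats, each with its own split and init."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = [train_spec.seed + i for i in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    rows, per_class_rows = [], []
    for i, seed in enumerate(seeds):
        _, cm, _ = run_once(cube, gt, config, train_spec, fractions, seed)
        rows.append({"repeat": i + 1, "seed": seed,
                     "oa": overall_accuracy(cm), "aa": average_accuracy(cm),
                     "kappa": kappa(cm)})
        per_class_rows.append(per_class_accuracy(cm))
    pc = np.stack(per_class_rows)
    per_class = pd.DataFrame({
        "mean": np.nanmean(pc, axis=0),
        "sd": np.nanstd(pc, axis=0, ddof=0),
    }, index=np.arange(1, pc.shape[1] + 1))
    return RepeatSummary(pd.DataFrame(rows), per_class)


# --------------------------------------------------------------- scene prediction

# 17-entry palette (background + up to 16 classes), RGB in [0, 1]
CLASS_PALETTE = np.array([
    [0.00, 0.00, 0.00], [0.89, 0.10, 0.11], [0.22, 0.49, 0.72],
    [0.30, 0.69, 0.29], [0.60, 0.31, 0.64], [1.00, 0.50, 0.00],
    [1.00, 1.00, 0.20], [0.65, 0.34, 0.16], [0.97, 0.51, 0.75],
    [0.60, 0.60, 0.60], [0.09, 0.75, 0.81], [0.40, 0.20, 0.60],
    [0.74, 0.72, 0.42], [0.86, 0.44, 0.58], [0.47, 0.67, 0.19],
    [0.30, 0.30, 0.49], [0.75, 0.94, 0.27],
])


def predict_map(model: SGTN, cube: HSICube, gt: GroundTruthMap | None,
                s: int | None = None, batch_size: int = 256) -> np.ndarray:
    """Predict a class for every pixel of the scene (1-based integer map)."""
    s = s if s is not None else model.config.s
    if cube.band_count != model.config.bands:
        raise ValueError(f"cube has {cube.band_count} bands; model expects "
                         f"{model.config.bands}")
    rows, cols, _ = cube.shape
    coords = np.argwhere(np.ones((rows, cols), dtype=bool))
    out = np.zeros(rows * cols, dtype=np.int64)
    for lo in range(0, len(coords), batch_size):
        X, _ = patch_arrays(cube, None, coords[lo:lo + batch_size], s)
        out[lo:lo + batch_size] = predict_label(_forward_batched(model, X))
    return out.reshape(rows, cols)


def render_map(class_map: np.ndarray, path=None,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Color a class map with the fixed palette; optionally mask label 0.

    ``mask`` is a label map whose zeros are painted background. Returns the
    RGB image; writes a PNG when ``path`` is given.
    """
    cmap = np.asarray(class_map).copy()
    if mask is not None:
        cmap[np.asarray(mask) == 0] = 0
    palette = CLASS_PALETTE
    if cmap.max() >= len(palette):     # extend deterministically if needed
        extra = cmap.max() + 1 - len(palette)
        rng = np.random.default_rng(12345)
        palette = np.vstack([palette, rng.uniform(0.2, 1.0, (extra, 3))])
    rgb = palette[cmap]
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        plt.imsave(path, rgb)
    return rgb
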