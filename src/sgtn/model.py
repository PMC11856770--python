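"""The assembled SGTN classifier.

Architecture (patch in, class logits out):

    patch (s, s, bands)
      -> 1x1 conv, 64 filters, ReLU          (spectral reduction)
      -> stage 1: MSIE(x) * SGA(x)           (weight map broadcast over channels)
      -> stage 2: MSIE(x) * SGA(x)
      -> global average pooling              (64-vector)
      -> FC 64->32, ReLU -> FC 32->classes   (logits)

Both stages consume the running feature map with independent parameters; the
SGA branch sees the same stage input as the MSIE branch and contributes only
its s x s weight map.  Ablation switches replace MSIE with a plain two-layer
3x3 convolution stack and/or drop SGA (equivalent to an all-ones map).

Reference patch sides: 13 for Indian Pines, 15 for Salinas and Pavia
University.  With the fixed widths (64 filters, FC hidden 32, MLP hidden
152, one head, depth one) the three benchmark configurations all land at
0.22 M trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import Conv2d, Linear, Module
from .msie import MSIEBlock, StandardConvBlock
from .nn import Tensor
from .sga import SGABlock

__all__ = ["ModelConfig", "SGTN", "build_sgtn", "count_parameters",
           "predict_label", "save_checkpoint", "load_checkpoint",
           "REFERENCE_CONFIGS"]

FORMAT_VERSION = "sgtn-checkpoint-1"


@dataclass
class ModelConfig:
    bands: int
    n_classes: int
    s: int = 13
    use_sga: bool = True
    use_msie: bool = True
    reduction_filters: int = 64
    fc_hidden: int = 32
    heads: int = 1
    depth: int = 1
    mlp_hidden: int = 152
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s % 2 != 1 or self.s < 1:
            raise ValueError("patch side s must be a positive odd integer")
        if self.bands < 1 or self.n_classes < 1:
            raise ValueError("bands and n_classes must be >= 1")


#: The three benchmark configurations (bands, classes, patch side).
REFERENCE_CONFIGS = {
    "indian_pines": ModelConfig(bands=200, n_classes=16, s=13),
    "salinas": ModelConfig(bands=204, n_classes=16, s=15),
    "pavia_university": ModelConfig(bands=103, n_classes=9, s=15),
}


class SGTN(Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        f = config.reduction_filters
        rng = np.random.default_rng(config.seed)
        self.reduction = Conv2d(config.bands, f, (1, 1), rng)
        extractor = MSIEBlock if config.use_msie else StandardConvBlock
        self.extractors = [extractor(f, rng), extractor(f, rng)]
        self.sgas = ([SGABlock(f, config.s, rng, heads=config.heads,
                               depth=config.depth,
                               mlp_hidden=config.mlp_hidden)
                      for _ in range(2)] if config.use_sga else [])
        self.fc1 = Linear(f, config.fc_hidden, rng)
        self.fc2 = Linear(config.fc_hidden, config.n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, s, s, bands) -> logits (N, n_classes); also accepts one patch."""
        single = x.ndim == 3
        if single:
            x = x.reshape((1,) + x.shape)
        cfg = self.config
        if x.shape[1:] != (cfg.s, cfg.s, cfg.bands):
            raise ValueError(f"expected patches of shape ({cfg.s}, {cfg.s}, "
                             f"{cfg.bands}), got {x.shape[1:]}")
        h = self.reduction(x).relu()
        for k, extractor in enumerate(self.extractors):
            main = extractor(h)
            if self.sgas:
                wmap = self.sgas[k](h)                     # (N, s, s)
                main = main * wmap.reshape(wmap.shape + (1,))
            h = main
        pooled = h.mean(axis=(1, 2))                       # (N, 64)
        logits = self.fc2(self.fc1(pooled).relu())
        return logits.reshape(logits.shape[1:]) if single else logits


def build_sgtn(config: ModelConfig) -> SGTN:
    return SGTN(config)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars (weights, biases, LN, w_p, w_c)."""
    return model.parameter_count()


def predict_label(logits: np.ndarray) -> int | np.ndarray:
    """Argmax class (1-based); ties break toward the lowest class index."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    if np.isnan(arr).any():
        raise ValueError("logits contain NaN")
    return arr.argmax(axis=-1) + 1


# ------------------------------------------------------------------ checkpointing


def save_checkpoint(model: SGTN, path) -> None:
    """Single-file archive of named arrays + the config as embedded JSON."""
    arrays = {name: t.data for name, t in model.named_parameters().items()}
    meta = {"format": FORMAT_VERSION, "config": asdict(model.config)}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> SGTN:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("format") != FORMAT_VERSION:
            raise ValueError("unrecognized checkpoint format")
        model = SGTN(ModelConfig(**meta["config"]))
        params = model.named_parameters()
        for name, tensor in params.items():
            if name not in archive:
                raise ValueError(f"checkpoint missing parameter {name!r}")
            tensor.data = archive[name].copy()
    return model
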