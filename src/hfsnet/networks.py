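"""The three segmentation architectures used by the hierarchical pipeline.

* 2D U-Net — encoder/decoder with skip connections; the large-tumor branch.
* 2D DenseU-Net — a U-Net whose convolution blocks are dense blocks with
  concatenative (tightly connected) paths; the liver, size-estimation and
  small-tumor models.
* 3D U-Net — volumetric variant pooling only in-plane, used by the fusion
  stage on fixed-depth Z patches.

All models are configurable in depth and width so that a "tiny" profile
(depth 3, base width 8) trains in seconds on one CPU while the same code
scales up.  Networks map ``(N, in_channels, *spatial)`` arrays to per-voxel
class probabilities (softmax over the class axis).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn

ARCHITECTURES = ("unet2d", "denseunet2d", "unet3d")

# initial foreground prior encoded in the head bias (see _UNet)
FG_PRIOR = 0.02


@dataclass
class NetConfig:
    """Architecture hyperparameters for one sub-model."""

    arch: str
    in_channels: int = 1
    out_classes: int = 2
    depth: int = 3
    base_width: int = 8
    growth_rate: int = 8  # dense blocks only
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.arch!r}; "
                             f"choose from {ARCHITECTURES}")
        if self.in_channels not in (1, 3, 5):
            raise ValueError("in_channels must be 1 (single phase), 3 (dynamic "
                             "stack) or 5 (fusion stack)")
        if self.out_classes < 2:
            raise ValueError("out_classes must be >= 2")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


# -- building blocks ---------------------------------------------------------

class _PlainBlock:
    """Two 3x3 convolutions with ReLU."""

    def __init__(self, cin, cout, nsp, rng):
        self.c1 = nn.ConvNd(cin, cout, 3, nsp, rng)
        self.c2 = nn.ConvNd(cout, cout, 3, nsp, rng)

    def __call__(self, x):
        return self.c2(self.c1(x).relu()).relu()

    @property
    def params(self):
        return self.c1.params + self.c2.params


class _DenseBlock:
    """Dense block: each layer's output is concatenated onto its input,
    followed by a 1x1 transition to the block width.  A growth rate of 0
    degenerates to a plain two-convolution block."""

    N_LAYERS = 2

    def __init__(self, cin, cout, growth, nsp, rng):
        self.growth = growth
        if growth <= 0:
            self.plain = _PlainBlock(cin, cout, nsp, rng)
            return
        self.plain = None
        self.layers = []
        cur = cin
        for _ in range(self.N_LAYERS):
            self.layers.append(nn.ConvNd(cur, growth, 3, nsp, rng))
            cur += growth
        self.transition = nn.ConvNd(cur, cout, 1, nsp, rng)

    def __call__(self, x):
        if self.plain is not None:
            return self.plain(x)
        feats = x
        for layer in self.layers:
            feats = nn.concat([feats, layer(feats).relu()], axis=1)
        return self.transition(feats).relu()

    @property
    def params(self):
        if self.plain is not None:
            return self.plain.params
        out = []
        for layer in self.layers:
            out += layer.params
        return out + self.transition.params


class _UNet:
    """Generic U-Net skeleton over 2 or 3 spatial dimensions."""

    def __init__(self, config: NetConfig, nsp: int, dense: bool):
        self.config = config
        self.nsp = nsp
        rng = np.random.default_rng(config.seed)
        widths = [config.base_width * 2 ** i for i in range(config.depth)]
        growth = config.growth_rate if dense else 0
        # pool only in-plane for 3D so shallow Z patches survive all levels
        self.pool_factors = (1, 2, 2) if nsp == 3 else (2, 2)

        def block(cin, cout):
            return _DenseBlock(cin, cout, growth, nsp, rng) if dense \
                else _PlainBlock(cin, cout, nsp, rng)

        self.enc = []
        cin = config.in_channels
        for w in widths:
            self.enc.append(block(cin, w))
            cin = w
        self.up_convs, self.dec = [], []
        for i in range(config.depth - 2, -1, -1):
            self.up_convs.append(nn.ConvNd(widths[i + 1], widths[i], 3, nsp, rng))
            self.dec.append(block(2 * widths[i], widths[i]))
        self.head = nn.ConvNd(widths[0], config.out_classes, 1, nsp, rng)
        # focal-loss style prior: start foreground rare (p ~ FG_PRIOR) so the
        # early background gradient does not swamp small-lesion learning
        self.head.b.data[1:] = np.log(FG_PRIOR / (1.0 - FG_PRIOR))

    # ------------------------------------------------------------------
    def forward_t(self, x: nn.Tensor) -> nn.Tensor:
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk(x)
            if i < len(self.enc) - 1:
                skips.append(x)
                x = nn.maxpool(x, self.pool_factors)
        for up, blk, skip in zip(self.up_convs, self.dec, reversed(skips)):
            x = up(nn.upsample_nearest(x, self.pool_factors)).relu()
            x = blk(nn.concat([skip, x], axis=1))
        return self.head(x).softmax(axis=1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self.forward_t(nn.Tensor(x)).data

    @property
    def params(self):
        out = []
        for blk in self.enc + self.dec:
            out += blk.params
        for up in self.up_convs:
            out += up.params
        return out + self.head.params

    # -- checkpoints ----------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float64)


class UNet2D(_UNet):
    def __init__(self, config):
        super().__init__(config, nsp=2, dense=False)


class DenseUNet2D(_UNet):
    def __init__(self, config):
        super().__init__(config, nsp=2, dense=True)


class UNet3D(_UNet):
    def __init__(self, config):
        super().__init__(config, nsp=3, dense=False)


_ARCH_CLASSES = {"unet2d": UNet2D, "denseunet2d": DenseUNet2D, "unet3d": UNet3D}


def build(config: NetConfig) -> _UNet:
    """Instantiate a model; weight initialization is deterministic in
    ``config.seed``."""
    return _ARCH_CLASSES[config.arch](config)


def predict_probs(model: _UNet, batch: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass returning per-voxel class probabilities.

    ``batch`` must be ``(N, in_channels, *spatial)`` with spatial sizes
    divisible by the pooling factors at every level.
    """
    batch = np.asarray(batch, dtype=np.float64)
    nsp = model.nsp
    if batch.ndim != 2 + nsp:
        raise ValueError(f"expected {2 + nsp}D batch, got shape {batch.shape}")
    if batch.shape[1] != model.config.in_channels:
        raise ValueError(f"expected {model.config.in_channels} channels, "
                         f"got {batch.shape[1]}")
    return model(batch)


def save_checkpoint(model: _UNet, path, extra: dict | None = None) -> None:
    """Write weights + NetConfig (+ optional training metadata) to an .npz."""
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> _UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build(NetConfig(**meta["config"]))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
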