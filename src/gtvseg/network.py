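"""Six-stage 3D U-Net with per-stage kernel control.

The architecture follows the classic U-Net layout: an encoder of
``n_stages`` resolution stages (two conv blocks each, channel count
doubling after every 2×2×2 max-pool) and a mirrored decoder in which each
upsampling step is a 1×1×1 conv block halving the channel count followed
by nearest-neighbor doubling of the spatial size, concatenation with the
encoder skip, and two more conv blocks. Every conv block is convolution →
instance normalization → ReLU; a final 1×1×1 convolution plus softmax
yields per-voxel class probabilities.

The per-stage kernel edge is configurable: with the default
``[3, 3, 3, 3, 1, 1]`` the two deepest (widest) stages use pointwise
convolutions, cutting the trainable-parameter total from roughly 86 to 14
million while leaving the receptive field at the deep stages to pooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import (
    Adam,
    ConvBlock,
    Conv3d,
    MaxPool2x,
    NearestUpsample2x,
    dice_loss_and_grad,
    softmax,
)

__all__ = ["NetworkConfig", "UNet3D", "build_unet", "count_parameters",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class NetworkConfig:
    """Per-stage channel/kernel configuration of the U-Net.

    ``base_width`` is the channel count at Stage 1; stage ``s`` (1-based)
    carries ``base_width * 2**(s-1)`` channels. ``kernel_by_stage`` gives
    the (odd) conv kernel edge per stage and applies to the decoder stage
    at the same resolution. ``instance_norm=False`` drops normalization
    from the conv blocks (used e.g. for strictly voxelwise test networks).
    """

    in_channels: int = 1
    out_classes: int = 3
    base_width: int = 32
    n_stages: int = 6
    kernel_by_stage: list[int] = field(default_factory=lambda: [3, 3, 3, 3, 1, 1])
    blocks_per_stage: int = 2
    instance_norm: bool = True

    def __post_init__(self):
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if len(self.kernel_by_stage) != self.n_stages:
            raise ValueError(
                f"kernel_by_stage has {len(self.kernel_by_stage)} entries "
                f"for {self.n_stages} stages"
            )
        if any(k < 1 or k % 2 == 0 for k in self.kernel_by_stage):
            raise ValueError("kernel edges must be odd and >= 1")
        if self.blocks_per_stage < 1 or self.base_width < 1:
            raise ValueError("blocks_per_stage and base_width must be >= 1")

    def stage_channels(self, s: int) -> int:
        """Channels at 0-based stage index ``s``."""
        return self.base_width * 2**s


class UNet3D:
    """The segmentation model; a callable returning per-voxel probabilities."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        ch = [cfg.stage_channels(s) for s in range(cfg.n_stages)]
        norm = cfg.instance_norm

        self.enc = []
        for s in range(cfg.n_stages):
            cin = cfg.in_channels if s == 0 else ch[s - 1]
            blocks = []
            for b in range(cfg.blocks_per_stage):
                blocks.append(
                    ConvBlock(cin if b == 0 else ch[s], ch[s], cfg.kernel_by_stage[s], rng, norm, dtype)
                )
            self.enc.append(blocks)
        self.pools = [MaxPool2x() for _ in range(cfg.n_stages - 1)]

        # decoder levels run from the deepest skip (stage n-1, 0-based n-2)
        # back up to stage 1
        self.dec = []
        for s in range(cfg.n_stages - 2, -1, -1):
            up_proj = ConvBlock(ch[s + 1], ch[s], 1, rng, norm, dtype)
            upsample = NearestUpsample2x()
            blocks = []
            for b in range(cfg.blocks_per_stage):
                blocks.append(
                    ConvBlock(2 * ch[s] if b == 0 else ch[s], ch[s], cfg.kernel_by_stage[s], rng, norm, dtype)
                )
            self.dec.append({"stage": s, "up_proj": up_proj, "upsample": upsample, "blocks": blocks})

        self.head = Conv3d(ch[0], cfg.out_classes, 1, rng, dtype)
        self._cache = None

    # -- parameters ---------------------------------------------------------
    def params(self):
        ps = []
        for blocks in self.enc:
            for b in blocks:
                ps.extend(b.params())
        for level in self.dec:
            ps.extend(level["up_proj"].params())
            for b in level["blocks"]:
                ps.extend(b.params())
        ps.extend(self.head.params())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape ``(N, out_classes, X, Y, Z)``."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, X, Y, Z) input, got {x.shape}"
            )
        div = 2 ** (self.cfg.n_stages - 1)
        if any(d % div for d in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {div} "
                f"for {self.cfg.n_stages} stages"
            )
        skips = []
        for s in range(self.cfg.n_stages):
            for b in self.enc[s]:
                x = b.forward(x, train=train)
            if s < self.cfg.n_stages - 1:
                skips.append(x)
                x = self.pools[s].forward(x, train=train)
        concat_splits = []
        for level in self.dec:
            x = level["up_proj"].forward(x, train=train)
            x = level["upsample"].forward(x, train=train)
            skip = skips[level["stage"]]
            concat_splits.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for b in level["blocks"]:
                x = b.forward(x, train=train)
        if train:
            self._cache = concat_splits
        return self.head.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from the logit gradient."""
        concat_splits = self._cache
        d = self.head.backward(dlogits)
        dskips = {}
        for level, csplit in zip(reversed(self.dec), reversed(concat_splits)):
            for b in reversed(level["blocks"]):
                d = b.backward(d)
            dskip, d = d[:, :csplit], d[:, csplit:]
            dskips[level["stage"]] = dskip
            d = level["upsample"].backward(d)
            d = level["up_proj"].backward(d)
        for s in range(self.cfg.n_stages - 1, -1, -1):
            if s < self.cfg.n_stages - 1:
                d = self.pools[s].backward(d)
                d = d + dskips[s]
            for b in reversed(self.enc[s]):
                d = b.backward(d)

    # -- convenience --------------------------------------------------------
    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (softmax over the logits)."""
        return softmax(self.forward(x, train=False), axis=1)

    __call__ = predict_probs

    def train_step(self, x: np.ndarray, onehot: np.ndarray, optimizer: Adam, lr: float) -> float:
        """One forward/backward/update on a batch; returns the Dice loss."""
        optimizer.zero_grad()
        logits = self.forward(x, train=True)
        loss, dlogits = dice_loss_and_grad(logits, onehot)
        self.backward(dlogits)
        optimizer.step(lr)
        return loss

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value[...] = a


def build_unet(cfg: NetworkConfig, seed: int = 0, dtype=np.float32) -> UNet3D:
    """Instantiate the U-Net described by ``cfg`` with seeded He init."""
    return UNet3D(cfg, seed=seed, dtype=dtype)


def count_parameters(cfg: NetworkConfig) -> int:
    """Total trainable parameters (conv weights/biases, norm affine) of
    :func:`build_unet` under ``cfg``."""
    return build_unet(cfg).n_parameters()


def save_checkpoint(model: UNet3D, path) -> None:
    """Serialize weights + config to an ``.npz`` checkpoint."""
    arrays = {f"p{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, _config=np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    ), **arrays)


def load_checkpoint(path) -> UNet3D:
    """Rebuild a model from an ``.npz`` checkpoint."""
    with np.load(path) as z:
        cfg = NetworkConfig(**json.loads(bytes(z["_config"].tobytes()).decode()))
        keys = sorted(k for k in z.files if k.startswith("p"))
        arrays = [z[k] for k in keys]
    model = build_unet(cfg)
    model.load_state_arrays(arrays)
    return model
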