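"""U-Net segmentation model f(x; Θ) and weight-state management.

The network follows the classic encoder/decoder layout with batch-normalised
double-conv blocks, 2x2 max-pool downsampling, learned 2x2 transposed-conv
upsampling and skip concatenation. Channel width doubles at every stage, so
with ``first_encoder_channels=16`` and ``depth=4`` the bottleneck carries
16 * 2**4 = 256 channels. The head is a 1x1 convolution to two class
logits; the foreground probability is the class-1 channel of a per-pixel
softmax.

Weights live in :class:`WeightSet` objects tagged with their role in the
mean-teacher scheme: ``pretrained`` (Θp), ``teacher`` (Θt) or ``student``
(Θs). A WeightSet is a plain dict of named arrays (trainable parameters and
batch-norm running statistics), so copying, EMA blending and optimiser
updates are all simple array arithmetic.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .nn import BatchNorm2d, Conv2d, ConvTranspose2d, Layer, MaxPool2d

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the U-Net."""

    first_encoder_channels: int = 16
    depth: int = 4
    in_channels: int = 3
    out_classes: int = 2

    def __post_init__(self) -> None:
        if self.first_encoder_channels < 1:
            raise ValueError("first_encoder_channels must be positive")
        if self.depth < 1:
            raise ValueError("depth must be at least 1")
        if self.out_classes != 2:
            raise ValueError("binary segmentation requires out_classes=2")

    def stage_channels(self) -> list[int]:
        """Channel width per encoder stage, index 0 .. depth (bottleneck)."""
        return [self.first_encoder_channels * 2 ** d
                for d in range(self.depth + 1)]

    def to_dict(self) -> dict:
        return {
            "first_encoder_channels": self.first_encoder_channels,
            "depth": self.depth,
            "in_channels": self.in_channels,
            "out_classes": self.out_classes,
        }


@dataclass
class WeightSet:
    """One complete network parameter state plus its mean-teacher role."""

    params: dict[str, np.ndarray]
    buffers: dict[str, np.ndarray]
    role: str = "pretrained"
    config: ModelConfig = field(default_factory=ModelConfig)

    VALID_ROLES = ("pretrained", "teacher", "student")

    def __post_init__(self) -> None:
        if self.role not in self.VALID_ROLES:
            raise ValueError(f"role must be one of {self.VALID_ROLES}")

    def copy(self, role: str | None = None) -> "WeightSet":
        """Deep copy; mutating the copy never touches the original."""
        return WeightSet(
            params={k: v.copy() for k, v in self.params.items()},
            buffers={k: v.copy() for k, v in self.buffers.items()},
            role=role if role is not None else self.role,
            config=self.config,
        )

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        yield from self.params.items()
        yield from self.buffers.items()

    def fingerprint(self) -> str:
        """Order-stable hash of every array, for mutation checks."""
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        for k in sorted(self.buffers):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.buffers[k]).tobytes())
        return h.hexdigest()


class _DoubleConv:
    """(conv3x3 -> BN -> ReLU) x 2; the ReLU is fused into the BN layer."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 input_block: bool = False) -> None:
        self.seq: list[Layer] = [
            Conv2d(in_ch, out_ch, 3, rng, bias=False,
                   track_input_grad=not input_block),
            BatchNorm2d(out_ch, relu=True),
            Conv2d(out_ch, out_ch, 3, rng, bias=False),
            BatchNorm2d(out_ch, relu=True),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.seq:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.seq):
            dout = layer.backward(dout)
        return dout


class UNet:
    """Configurable U-Net over float32 channels-last (NHWC) tensors."""

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.stage_channels()

        self.enc: list[_DoubleConv] = []
        prev = cfg.in_channels
        for d in range(cfg.depth):
            self.enc.append(_DoubleConv(prev, ch[d], rng, input_block=d == 0))
            prev = ch[d]
        self.pool = [MaxPool2d() for _ in range(cfg.depth)]
        self.bottleneck = _DoubleConv(ch[cfg.depth - 1], ch[cfg.depth], rng)
        self.up: list[ConvTranspose2d] = []
        self.dec: list[_DoubleConv] = []
        for d in range(cfg.depth - 1, -1, -1):
            self.up.append(ConvTranspose2d(ch[d + 1], ch[d], rng))
            self.dec.append(_DoubleConv(2 * ch[d], ch[d], rng))
        self.head = Conv2d(ch[0], cfg.out_classes, 1, rng)
        self._skip_shapes: list[tuple[int, ...]] | None = None

    # -- parameter plumbing -------------------------------------------------

    def _named_layers(self) -> Iterator[tuple[str, Layer]]:
        for d, block in enumerate(self.enc):
            for i, layer in enumerate(block.seq):
                yield f"enc{d}.{i}", layer
        for i, layer in enumerate(self.bottleneck.seq):
            yield f"bottleneck.{i}", layer
        for d, (up, block) in enumerate(zip(self.up, self.dec)):
            yield f"up{d}", up
            for i, layer in enumerate(block.seq):
                yield f"dec{d}.{i}", layer
        yield "head", self.head

    def state(self, role: str = "pretrained") -> WeightSet:
        """Snapshot of all parameters and buffers (copies)."""
        params, buffers = {}, {}
        for name, layer in self._named_layers():
            for k, v in layer.params.items():
                params[f"{name}.{k}"] = v.copy()
            for k, v in layer.buffers.items():
                buffers[f"{name}.{k}"] = v.copy()
        return WeightSet(params, buffers, role=role, config=self.cfg)

    def load_state(self, ws: WeightSet) -> None:
        for name, layer in self._named_layers():
            for k in layer.params:
                layer.params[k][...] = ws.params[f"{name}.{k}"]
            for k in layer.buffers:
                layer.buffers[k][...] = ws.buffers[f"{name}.{k}"]

    def parameters(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """(name, param, grad) triples of trainable parameters."""
        for name, layer in self._named_layers():
            for k in layer.params:
                yield f"{name}.{k}", layer.params[k], layer.grads[k]

    def zero_grad(self) -> None:
        for _, layer in self._named_layers():
            layer.zero_grad()

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Two-class logits (N, H, W, 2) for a float32 NHWC batch in [0, 1]."""
        if x.ndim != 4 or x.shape[3] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N,H,W,{self.cfg.in_channels}), got {x.shape}")
        h, w = x.shape[1], x.shape[2]
        div = 2 ** self.cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial dims {h}x{w} must be divisible by 2**depth={div}")
        skips = []
        for block, pool in zip(self.enc, self.pool):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_shapes = [s.shape for s in skips]
        for up, block, skip in zip(self.up, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = block.forward(np.concatenate([skip, x], axis=3), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * len(self.enc)
        for idx in range(len(self.dec) - 1, -1, -1):
            dcat = self.dec[idx].backward(d)
            skip_ch = dcat.shape[3] // 2
            dskips[len(self.enc) - 1 - idx] = dcat[..., :skip_ch]
            d = self.up[idx].backward(
                np.ascontiguousarray(dcat[..., skip_ch:]))
        d = self.bottleneck.backward(d)
        for block, pool, dskip in zip(reversed(self.enc),
                                      reversed(self.pool),
                                      reversed(dskips)):
            d = pool.backward(d)
            d = block.backward(d + dskip)


def softmax_foreground(logits: np.ndarray) -> np.ndarray:
    """Per-pixel two-class softmax; returns the class-1 (lesion) channel."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e[..., 1] / e.sum(axis=-1)
    return p.astype(np.float32, copy=False)


def init_model(cfg: ModelConfig, seed: int = 0) -> WeightSet:
    """Fresh Kaiming-initialised weights Θp; deterministic under seed."""
    return UNet(cfg, seed=seed).state(role="pretrained")


def forward(x: np.ndarray, ws: WeightSet,
            model: UNet | None = None) -> np.ndarray:
    """Foreground-probability maps for a batch, in inference mode.

    ``x`` is (N, H, W, 3) in [0, 1] (channels-first input is transposed).
    Inference mode never updates batch-norm statistics; the returned array
    is (N, H, W) with values in [0, 1].
    """
    if model is None:
        model = UNet(ws.config, seed=0)
    model.load_state(ws)
    xb = as_batch(x)
    return softmax_foreground(model.forward_logits(xb, train=False))


def as_batch(x: np.ndarray) -> np.ndarray:
    """Accept (N,H,W,3) or (N,3,H,W) float images; return float32 NHWC."""
    if x.ndim != 4:
        raise ValueError(f"expected a 4-d batch, got shape {x.shape}")
    if x.shape[1] == 3 and x.shape[-1] != 3:
        x = x.transpose(0, 2, 3, 1)
    return np.ascontiguousarray(x, dtype=np.float32)


# -- checkpoints ------------------------------------------------------------
# A checkpoint is a zip archive: 'meta.json' (format version, ModelConfig,
# role, iteration, validation Dice) + one raw .npy per array.


def save_checkpoint(path, ws: WeightSet, iteration: int = 0,
                    val_dice: float | None = None) -> None:
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": ws.config.to_dict(),
        "role": ws.role,
        "iteration": int(iteration),
        "val_dice": None if val_dice is None else float(val_dice),
        "params": sorted(ws.params),
        "buffers": sorted(ws.buffers),
    }
    def _entry(name: str) -> zipfile.ZipInfo:
        # fixed timestamp so identical states give identical files
        return zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))

    try:
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            zf.writestr(_entry("meta.json"), json.dumps(meta, indent=1))
            for group, arrays in (("params", ws.params),
                                  ("buffers", ws.buffers)):
                for k, v in arrays.items():
                    buf = io.BytesIO()
                    np.save(buf, v)
                    zf.writestr(_entry(f"{group}/{k}.npy"), buf.getvalue())
    except OSError as exc:
        raise OSError(f"failed to write checkpoint to {path!r}: {exc}") from exc


def load_checkpoint(path) -> tuple[WeightSet, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta['format_version']}")
        cfg = ModelConfig(**meta["config"])
        params = {k: np.load(io.BytesIO(zf.read(f"params/{k}.npy")))
                  for k in meta["params"]}
        buffers = {k: np.load(io.BytesIO(zf.read(f"buffers/{k}.npy")))
                   for k in meta["buffers"]}
    ws = WeightSet(params, buffers, role=meta["role"], config=cfg)
    return ws, meta
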