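"""ShrapOD: SqueezeNet-style backbone with two YOLO detection heads.

Topology: a stem convolution block (conv + ReLU + max pool), four
shared Fire blocks, then a class pathway of five more Fire blocks whose
last block (Fire 9, stride 32) feeds the coarse detection head through
a conv + batch-norm + ReLU block.  The fine head fuses the Fire-9
output — passed through a feature-resizing conv block and ×2 nearest
upsampling — with the Fire-8 output (stride 16), followed by a final
conv block.  Each head emits, per grid cell and per anchor,
``(tx, ty, tw, th, objectness, class scores)``.

Channel widths follow SqueezeNet v1.1 scaled by a width multiplier so
the same graph runs at desk scale on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .anchors import AnchorSet
from .nn import (BatchNorm2d, Conv2d, MaxPool2, Param, ReLU,
                 UpsampleNearest2, concat_channels, split_channels)

__all__ = ["ArchSpec", "Fire", "ShrapOD", "build_model",
           "save_model", "load_model", "HEAD_STRIDES"]

#: Output strides of the (coarse, fine) detection heads.
HEAD_STRIDES: tuple[int, int] = (32, 16)

# SqueezeNet v1.1 squeeze/expand widths for the eight canonical Fire
# modules plus the extra ninth used here.
_FIRE_WIDTHS = [(16, 64), (16, 64), (32, 128), (32, 128),
                (48, 192), (48, 192), (64, 256), (64, 256), (64, 256)]


@dataclass(frozen=True)
class ArchSpec:
    """Structural hyperparameters of the detector."""

    input_size: int = 512
    n_classes: int = 4
    width: float = 1.0
    stem_channels: int = 64
    head_channels: int = 256
    resize_channels: int = 128

    def __post_init__(self) -> None:
        if self.input_size % max(HEAD_STRIDES) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by head "
                f"strides {HEAD_STRIDES}")
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.width <= 0:
            raise ValueError("width multiplier must be positive")

    def ch(self, base: int) -> int:
        return max(4, int(round(base * self.width)))

    @property
    def grid_sizes(self) -> tuple[int, int]:
        return tuple(self.input_size // s for s in HEAD_STRIDES)

    @classmethod
    def desk(cls, **kwargs) -> "ArchSpec":
        """Reduced-width 256 px profile for CPU-scale training."""
        defaults = dict(input_size=256, width=0.25)
        defaults.update(kwargs)
        return cls(**defaults)


class Fire:
    """SqueezeNet Fire module: 1×1 squeeze → parallel 1×1/3×3 expands.

    Both expand paths are ReLU-activated and depth-concatenated.
    """

    def __init__(self, in_ch: int, squeeze: int, expand: int,
                 rng: np.random.Generator):
        self.squeeze = Conv2d(in_ch, squeeze, 1, rng=rng)
        self.s_relu = ReLU()
        self.e1 = Conv2d(squeeze, expand, 1, rng=rng)
        self.e1_relu = ReLU()
        self.e3 = Conv2d(squeeze, expand, 3, rng=rng)
        self.e3_relu = ReLU()
        self.out_ch = 2 * expand

    def params(self) -> list[Param]:
        return self.squeeze.params() + self.e1.params() + self.e3.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        s = self.s_relu.forward(self.squeeze.forward(x, train), train)
        a = self.e1_relu.forward(self.e1.forward(s, train), train)
        b = self.e3_relu.forward(self.e3.forward(s, train), train)
        return concat_channels(a, b)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        da, db = split_channels(dout, [self.e1.out_ch, self.e3.out_ch])
        ds = self.e1.backward(self.e1_relu.backward(da))
        ds = ds + self.e3.backward(self.e3_relu.backward(db))
        return self.squeeze.backward(self.s_relu.backward(ds))


class _ConvBlock:
    """conv → batch norm → ReLU (the head conv blocks)."""

    def __init__(self, in_ch: int, out_ch: int, k: int,
                 rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, k, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()
        self.out_ch = out_ch

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dout):
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


class ShrapOD:
    """The two-headed single-stage detector."""

    def __init__(self, arch: ArchSpec, anchors: AnchorSet, seed: int = 0):
        if len(anchors.fine) == 0:
            raise ValueError("fine head needs at least one anchor")
        self.arch = arch
        self.anchors = anchors
        rng = np.random.default_rng(seed)
        ch = arch.ch

        self.stem = Conv2d(3, ch(arch.stem_channels), 3, stride=2, rng=rng)
        self.stem_relu = ReLU()
        self.pools = [MaxPool2() for _ in range(4)]

        widths = [(ch(s), ch(e)) for s, e in _FIRE_WIDTHS]
        fires: list[Fire] = []
        in_ch = ch(arch.stem_channels)
        for s, e in widths:
            fires.append(Fire(in_ch, s, e, rng))
            in_ch = 2 * e
        self.fires = fires

        f8_ch = fires[7].out_ch
        f9_ch = fires[8].out_ch
        n_out = 5 + arch.n_classes
        self.feature_block = _ConvBlock(f9_ch, ch(arch.head_channels), 3, rng)
        self.out_coarse = Conv2d(self.feature_block.out_ch,
                                 len(anchors.coarse) * n_out, 1, rng=rng)

        self.resize_block = _ConvBlock(f9_ch, ch(arch.resize_channels), 1, rng)
        self.upsample = UpsampleNearest2()
        self.backend_block = _ConvBlock(self.resize_block.out_ch + f8_ch,
                                        ch(arch.head_channels), 3, rng)
        self.out_fine = Conv2d(self.backend_block.out_ch,
                               len(anchors.fine) * n_out, 1, rng=rng)
        self._f8_ch = f8_ch

    # -- parameter plumbing ---------------------------------------------------
    def params(self) -> list[Param]:
        ps = self.stem.params()
        for f in self.fires:
            ps += f.params()
        for blk in (self.feature_block, self.out_coarse, self.resize_block,
                    self.backend_block, self.out_fine):
            ps += blk.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Run the network on (N, 3, S, S) float32 input.

        Returns ``[coarse, fine]`` raw head outputs of shape
        ``(N, A_h * (5 + C), G_h, G_h)``.
        """
        if x.shape[2] != self.arch.input_size or x.shape[3] != self.arch.input_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} != {self.arch.input_size}")
        t = self.stem_relu.forward(self.stem.forward(x, train), train)
        t = self.pools[0].forward(t, train)                       # /4
        t = self.fires[1].forward(self.fires[0].forward(t, train), train)
        t = self.pools[1].forward(t, train)                       # /8
        t = self.fires[3].forward(self.fires[2].forward(t, train), train)
        t = self.pools[2].forward(t, train)                       # /16
        for f in self.fires[4:8]:
            t = f.forward(t, train)
        f8 = t                                                    # /16
        t = self.pools[3].forward(f8, train)                      # /32
        f9 = self.fires[8].forward(t, train)

        feat = self.feature_block.forward(f9, train)
        coarse = self.out_coarse.forward(feat, train)

        r = self.resize_block.forward(f9, train)
        r = self.upsample.forward(r, train)
        fused = concat_channels(r, f8)
        b = self.backend_block.forward(fused, train)
        fine = self.out_fine.forward(b, train)
        return [coarse, fine]

    def backward(self, douts: list[np.ndarray]) -> None:
        d_coarse, d_fine = douts
        db = self.backend_block.backward(self.out_fine.backward(d_fine))
        dr, df8_a = split_channels(db, [self.resize_block.out_ch, self._f8_ch])
        df9_a = self.resize_block.backward(self.upsample.backward(dr))

        dfeat = self.out_coarse.backward(d_coarse)
        df9_b = self.feature_block.backward(dfeat)

        d = self.fires[8].backward(df9_a + df9_b)
        d = self.pools[3].backward(d) + df8_a
        for f in reversed(self.fires[4:8]):
            d = f.backward(d)
        d = self.pools[2].backward(d)
        d = self.fires[2].backward(self.fires[3].backward(d))
        d = self.pools[1].backward(d)
        d = self.fires[0].backward(self.fires[1].backward(d))
        d = self.pools[0].backward(d)
        self.stem.backward(self.stem_relu.backward(d))

    def batchnorms(self) -> list[BatchNorm2d]:
        return [self.feature_block.bn, self.resize_block.bn,
                self.backend_block.bn]


def build_model(arch: ArchSpec, anchors: AnchorSet, seed: int = 0) -> ShrapOD:
    """Instantiate the detector with seeded He-normal initialisation."""
    return ShrapOD(arch, anchors, seed=seed)


def save_model(model: ShrapOD, path) -> None:
    """Serialise parameters + running stats + architecture to ``.npz``."""
    arrays = {f"param_{i:03d}": p.value for i, p in enumerate(model.params())}
    for i, bn in enumerate(model.batchnorms()):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    meta = {
        "arch": asdict(model.arch),
        "anchors": [list(a) for a in model.anchors.anchors],
        "n_coarse": model.anchors.n_coarse,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> ShrapOD:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arch = ArchSpec(**meta["arch"])
        anchors = AnchorSet(tuple(tuple(a) for a in meta["anchors"]),
                            meta["n_coarse"])
        model = ShrapOD(arch, anchors)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i:03d}"]
        for i, bn in enumerate(model.batchnorms()):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
    return model
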