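"""Encoder-decoder backbones and the three task networks.

One shared U-shaped architecture — convolution, batch normalisation and
PReLU with residual connections — instantiated three times:

* ``CenteringNet``: whole workspace volume in, single-channel heatmap out;
  the heatmap is a Gaussian bump over the LV-myocardium centre of mass and
  the crop centre is its argmax.
* ``SegmentationNet``: 2D, per-slice; cropped slice in, 4-channel softmax
  over {background, RV, myocardium, LV cavity} out.
* ``MotionNet``: 3D; a concatenated (reference, moving) frame pair in,
  3-channel displacement field out (voxel units).

Through-plane kernel extent ``kz`` is 1 or 3; pooling and upsampling always
act in-plane only, respecting the anisotropic short-axis geometry (few,
thick slices).  With ``kz = 1`` no operation mixes slices, so the network
commutes with slice permutation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .engine import Tensor, concat, maxpool_inplane, upsample_inplane
from .layers import BatchNorm, Conv, Module, PReLU

__all__ = ["NetworkConfig", "build_backbone", "CenteringNet", "SegmentationNet",
           "MotionNet", "softmax_channels", "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass
class NetworkConfig:
    kz: int = 1                 # through-plane kernel extent (1 or 3)
    base_filters: int = 16
    depth: int = 4              # number of resolution levels
    residual: bool = True
    batch_norm: bool = True
    seed: int = 0
    dtype: str = "float32"      # parameter/activation precision

    def __post_init__(self):
        if self.kz not in (1, 3):
            raise ValueError("kz must be 1 or 3")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")


class _ResBlock(Module):
    def __init__(self, in_ch, out_ch, kernel, cfg: NetworkConfig,
                 rng: np.random.Generator):
        dt = np.dtype(cfg.dtype).type
        self.conv1 = Conv(in_ch, out_ch, kernel, rng, dtype=dt)
        self.bn1 = BatchNorm(out_ch, dtype=dt) if cfg.batch_norm else None
        self.act1 = PReLU(out_ch, dtype=dt)
        self.conv2 = Conv(out_ch, out_ch, kernel, rng, dtype=dt)
        self.bn2 = BatchNorm(out_ch, dtype=dt) if cfg.batch_norm else None
        self.act2 = PReLU(out_ch, dtype=dt)
        self.residual = cfg.residual
        self.skip = Conv(in_ch, out_ch, (1,) * len(kernel), rng, dtype=dt) \
            if (cfg.residual and in_ch != out_ch) else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h)
        h = self.act1(h)
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h)
        if self.residual:
            s = self.skip(x) if self.skip is not None else x
            h = h + s
        return self.act2(h)


class Backbone(Module):
    """U-shaped encoder-decoder with in-plane pooling and skip connections."""

    def __init__(self, cfg: NetworkConfig, in_channels: int, out_channels: int,
                 dimensionality: int, head_scale: float = 1.0):
        if dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        rng = np.random.default_rng(cfg.seed)
        kernel = (3, 3) if dimensionality == 2 else (3, 3, cfg.kz)
        self.cfg = cfg
        self.dimensionality = dimensionality
        widths = [cfg.base_filters * 2**i for i in range(cfg.depth)]

        self.enc = []
        ch = in_channels
        for w in widths:
            self.enc.append(_ResBlock(ch, w, kernel, cfg, rng))
            ch = w
        self.dec = []
        for i in range(cfg.depth - 2, -1, -1):
            self.dec.append(_ResBlock(ch + widths[i], widths[i], kernel, cfg, rng))
            ch = widths[i]
        self.head = Conv(ch, out_channels, (1,) * dimensionality, rng,
                         dtype=np.dtype(cfg.dtype).type)
        self.head.weight.data *= head_scale
        self.out_channels = out_channels

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n_pool = cfg.depth - 1
        for ax in (2, 3):
            if x.shape[ax] % 2**n_pool:
                raise ValueError(
                    f"in-plane size {x.shape[2:4]} not divisible by {2**n_pool}")
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = maxpool_inplane(h)
        for block, s in zip(self.dec, reversed(skips)):
            h = upsample_inplane(h)
            h = concat([h, s], axis=1)
            h = block(h)
        return self.head(h)


def build_backbone(cfg: NetworkConfig, in_channels: int, out_channels: int,
                   dimensionality: int, head_scale: float = 1.0) -> Backbone:
    return Backbone(cfg, in_channels, out_channels, dimensionality, head_scale)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel axis (axis 1), numerically stabilised."""
    shift = np.max(x.data, axis=1, keepdims=True)     # constant wrt autodiff
    e = (x - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


class CenteringNet(Module):
    """Workspace volume -> centre heatmap of equal size (non-negative)."""

    def __init__(self, cfg: NetworkConfig):
        self.net = build_backbone(cfg, 1, 1, dimensionality=3)
        self.cfg = cfg

    def __call__(self, x: Tensor) -> Tensor:
        return self.net(x)

    def forward_volume(self, values: np.ndarray) -> np.ndarray:
        """Inference on one normalised (nx, ny, nz) volume -> heatmap."""
        self.eval()
        out = self(Tensor(values[None, None]))
        heat = np.maximum(out.data[0, 0], 0.0)
        if not np.all(np.isfinite(heat)):
            raise FloatingPointError("non-finite heatmap")
        return heat

    @staticmethod
    def argmax_center(heatmap: np.ndarray) -> tuple[int, int, int]:
        """Crop centre = argmax voxel; ties -> lowest linear index."""
        idx = int(np.argmax(heatmap))
        return tuple(int(i) for i in np.unravel_index(idx, heatmap.shape))


class SegmentationNet(Module):
    """Cropped 2D slice -> per-pixel class probabilities (4 channels)."""

    def __init__(self, cfg: NetworkConfig):
        self.net = build_backbone(cfg, 1, 4, dimensionality=2)
        self.cfg = cfg

    def __call__(self, x: Tensor) -> Tensor:
        return softmax_channels(self.net(x))

    def forward_slices(self, slices: np.ndarray) -> np.ndarray:
        """Inference on (n_slices, nx, ny) -> (n_slices, 4, nx, ny) probs."""
        self.eval()
        return self(Tensor(slices[:, None])).data

    def segment_volume(self, values: np.ndarray) -> np.ndarray:
        """Hard 4-class labels for a (nx, ny, nz) volume, slice-batched."""
        stack = np.moveaxis(values, 2, 0)                  # (nz, nx, ny)
        probs = self.forward_slices(stack)
        labels = np.argmax(probs, axis=1)                  # (nz, nx, ny)
        return np.moveaxis(labels, 0, 2).astype(np.int16)


class MotionNet(Module):
    """(reference, moving) pair -> 3-channel displacement field, voxel units.

    The output head is initialised near zero so the untrained network starts
    close to the identity transform.
    """

    def __init__(self, cfg: NetworkConfig):
        self.net = build_backbone(cfg, 2, 3, dimensionality=3, head_scale=1e-2)
        self.cfg = cfg

    def __call__(self, x: Tensor) -> Tensor:
        return self.net(x)

    def forward_pair(self, v0: np.ndarray, vt: np.ndarray) -> np.ndarray:
        """Inference on one normalised frame pair -> (3, nx, ny, nz)."""
        self.eval()
        if v0.shape != vt.shape:
            raise ValueError("frame pair must share a grid")
        inp = np.stack([v0, vt])[None]
        return self(Tensor(inp)).data[0]


_NET_KINDS = {"center": CenteringNet, "segment": SegmentationNet, "motion": MotionNet}


def make_network(kind: str, cfg: NetworkConfig) -> Module:
    try:
        return _NET_KINDS[kind](cfg)
    except KeyError:
        raise ValueError(f"unknown network kind {kind!r}") from None


def save_checkpoint(path: str | Path, net: Module, kind: str,
                    cfg: NetworkConfig, seed: int | None = None) -> None:
    """Weights as .npz with a JSON sidecar recording the configuration."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, **arrays)
    meta = {"kind": kind, "config": dataclasses.asdict(cfg), "seed": seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[Module, str, NetworkConfig]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig(**meta["config"])
    net = make_network(meta["kind"], cfg)
    with np.load(path) as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    net.load_state_arrays(arrays)
    net.eval()
    return net, meta["kind"], cfg
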