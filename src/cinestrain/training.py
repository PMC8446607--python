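"""Training loops, pairing schemes, heatmap targets, and augmentation.

Training follows one protocol for all three networks: Adam with
learning rate 1e-4 and betas (0.9, 0.999), batch size 80 for the centering
and segmentation networks and 5 for the motion network, random
initialisation from a single master seed that also drives data order and
augmentation.  The motion network trains on (ED, ED) and (ED, ES) frame
pairs only — the identity pair teaches the network the identity transform,
the ED-ES pair the full contraction.

Augmentation acts strictly in-plane: random rotation, translation,
mirroring along x and y, and gamma contrast correction (intensities only).
When a ground-truth displacement accompanies a sample its in-plane vector
components are rotated/mirrored consistently with the grid.
"""

from __future__ import annotations

import dataclasses
import gc
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import CineSequence, SegMask, normalize_intensity
from .losses import LossWeights, cce_loss, mdc_loss, mse_loss
from .nn.backbone import MotionNet, NetworkConfig, make_network
from .nn.engine import Tensor
from .nn.layers import Adam

__all__ = ["TrainConfig", "gaussian_target", "augment", "make_pairs",
           "train_network", "infer_sequence", "save_history"]


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 80           # 5 for the motion network
    epochs: int = 300
    seed: int = 0
    augment: bool = False
    rotation_deg: float = 15.0
    translation_vox: float = 10.0
    gamma_range: tuple[float, float] = (0.7, 1.4)
    heatmap_sigma_mm: float = 10.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 < self.gamma_range[0] <= self.gamma_range[1]):
            raise ValueError("gamma range must lie in (0, inf)")


def gaussian_target(mask: SegMask, sigma_mm: float = 10.0) -> np.ndarray:
    """Ground-truth centre heatmap: isotropic (in mm) Gaussian, peak 1,
    centred on the myocardium centre of mass."""
    from .grids import LABEL_LVM

    lvm = mask.labels == LABEL_LVM
    if not lvm.any():
        raise ValueError("mask has no myocardium voxels")
    centroid = np.array(np.nonzero(lvm), dtype=np.float64).mean(axis=1)
    g = mask.grid
    coords = np.meshgrid(*[np.arange(s) for s in g.shape], indexing="ij")
    d2 = sum(((c - m) * sp) ** 2
             for c, m, sp in zip(coords, centroid, g.spacing))
    heat = np.exp(-d2 / (2.0 * sigma_mm**2))
    return heat / heat.max()


# ---------------------------------------------------------------------------
# Augmentation (in-plane only)
# ---------------------------------------------------------------------------


def augment(sample: dict, rng: np.random.Generator,
            config: TrainConfig | None = None) -> dict:
    """Apply one consistent in-plane transform to every array of a sample.

    ``sample`` maps "volumes" -> list of intensity arrays, "masks" -> list
    of label arrays, optionally "displacement" -> (3, nx, ny, nz) field.
    Gamma correction applies to intensities only; the z axis is never
    touched.
    """
    cfg = config or TrainConfig()
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    shift = rng.uniform(-cfg.translation_vox, cfg.translation_vox, size=2)
    mirror_x = bool(rng.integers(2))
    mirror_y = bool(rng.integers(2))
    gamma = rng.uniform(*cfg.gamma_range)
    return _apply_transform(sample, angle, shift, mirror_x, mirror_y, gamma)


def _tf_array(a: np.ndarray, angle: float, shift, mx: bool, my: bool,
              order: int) -> np.ndarray:
    out = a
    if angle != 0.0:
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False,
                             order=order, mode="nearest")
    if shift[0] or shift[1]:
        sh = [shift[0], shift[1]] + [0.0] * (a.ndim - 2)
        out = ndimage.shift(out, sh, order=order, mode="nearest")
    if mx:
        out = np.flip(out, axis=0)
    if my:
        out = np.flip(out, axis=1)
    return np.ascontiguousarray(out)


def _apply_transform(sample: dict, angle: float, shift, mx: bool, my: bool,
                     gamma: float) -> dict:
    out: dict = {}
    vols = []
    for v in sample.get("volumes", []):
        tv = _tf_array(v, angle, shift, mx, my, order=1)
        tv = np.clip(tv, 0.0, None) ** gamma
        vols.append(tv)
    out["volumes"] = vols
    out["masks"] = [_tf_array(m.astype(np.float64), angle, shift, mx, my,
                              order=0).astype(m.dtype)
                    for m in sample.get("masks", [])]
    if "displacement" in sample and sample["displacement"] is not None:
        u = sample["displacement"]
        comps = [_tf_array(u[c], angle, shift, mx, my, order=1) for c in range(3)]
        th = np.deg2rad(angle)
        # image rotated by +angle about z: rotate in-plane vectors the same way
        ux = np.cos(th) * comps[0] - np.sin(th) * comps[1]
        uy = np.sin(th) * comps[0] + np.cos(th) * comps[1]
        if mx:
            ux = -ux
        if my:
            uy = -uy
        out["displacement"] = np.stack([ux, uy, comps[2]])
    return out


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


def make_pairs(sequence: CineSequence, masks: list[SegMask]
               ) -> list[tuple[np.ndarray, np.ndarray, SegMask, SegMask]]:
    """(ED, ED) and (ED, ES) training pairs with normalised intensities."""
    es = sequence.es_index
    if es is None:
        raise ValueError("sequence has no ES index; run ES detection first")
    if es == 0:
        raise ValueError("ES coincides with ED; degenerate sequence")
    v0 = normalize_intensity(sequence.frames[0].values)
    ves = normalize_intensity(sequence.frames[es].values)
    return [(v0, v0, masks[0], masks[0]), (v0, ves, masks[0], masks[es])]


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_network(kind: str, dataset: list, config: TrainConfig,
                  net_config: NetworkConfig | None = None,
                  loss_weights: LossWeights | None = None,
                  dr: tuple[float, float, float] = (1.0, 1.0, 1.0),
                  segment_loss: str = "mdc",
                  anatomical_mode: str = "mdc",
                  on_epoch_end=None,
                  ) -> tuple[object, list[float]]:
    """Train one network; returns (network, per-epoch mean loss history).

    Dataset items by kind:
      center:    (volume_values, target_heatmap)
      segment: (slice_values, one-hot target (4, nx, ny))
      motion: (v0, vt, m0 one-hot (4,...), mt one-hot (4,...))

    ``on_epoch_end(epoch, net)``, if given, is called after every epoch —
    useful for checkpoint snapshots or custom logging.
    """
    if not dataset:
        raise ValueError("empty dataset")
    net_config = net_config or NetworkConfig(seed=config.seed)
    net_config = dataclasses.replace(net_config, seed=config.seed)
    net = make_network(kind, net_config)
    opt = Adam(net.parameters(), lr=config.learning_rate,
               betas=config.adam_betas)
    rng = np.random.default_rng(config.seed + 1)
    weights = loss_weights or LossWeights()

    history: list[float] = []
    net.train()
    for epoch in range(config.epochs):
        losses = []
        for idx in _batches(len(dataset), config.batch_size, rng):
            batch = [dataset[i] for i in idx]
            loss = _batch_loss(kind, net, batch, weights, dr,
                               segment_loss, anatomical_mode)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss while training {kind}")
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        del loss
        if epoch % 4 == 3 or epoch == config.epochs - 1:
            gc.collect()   # training graphs may contain reference cycles
        history.append(float(np.mean(losses)))
        if on_epoch_end is not None:
            on_epoch_end(epoch, net)
    net.eval()
    return net, history


def _batch_loss(kind: str, net, batch, weights: LossWeights, dr,
                segment_loss: str, anatomical_mode: str) -> Tensor:
    dt = np.dtype(net.cfg.dtype)

    def stack(i, channel=False):
        a = np.stack([b[i] for b in batch]).astype(dt, copy=False)
        return a[:, None] if channel else a

    if kind == "center":
        return mse_loss(net(Tensor(stack(0, True))), Tensor(stack(1, True)))
    if kind == "segment":
        pred = net(Tensor(stack(0, True)))
        fn = mdc_loss if segment_loss == "mdc" else cce_loss
        return fn(Tensor(stack(1)), pred, channel_axis=1)
    if kind == "motion":
        v0, vt = stack(0, True), stack(1, True)
        m0, mt = stack(2), stack(3)
        u = net(Tensor(np.concatenate([v0, vt], axis=1)))
        return _motion_fused_loss(v0, vt, m0, mt, u, weights, dr,
                                  anatomical_mode)
    raise ValueError(f"unknown network kind {kind!r}")


def _motion_fused_loss(v0, vt, m0, mt, u: Tensor, weights: LossWeights, dr,
                       anatomical_mode: str) -> Tensor:
    """Motion loss with the moving frame and its mask channels warped by a
    single spatial transform (numerically identical to evaluating the
    intensity and anatomical terms separately)."""
    from .losses import smoothness_loss
    from .nn.engine import warp3d

    moving = Tensor(np.concatenate([vt, mt], axis=1))
    warped = warp3d(moving, u)
    wv, wm = warped[:, 0:1], warped[:, 1:5]
    li = (Tensor(v0) - wv).abs().mean()
    fn = mdc_loss if anatomical_mode == "mdc" else cce_loss
    la = fn(Tensor(m0), wm, channel_axis=1)
    ls = smoothness_loss(u, dr=dr)
    return weights.lambda_i * li + weights.lambda_a * la + weights.lambda_s * ls


def infer_sequence(net: MotionNet, sequence: CineSequence) -> list[np.ndarray]:
    """Motion fields u_t for every frame from (V0, Vt) pairs.

    The t = 0 field is the model's output for the identity pair (reported
    as-is; the strain engine applies its own zero reference at ED).
    """
    v0 = normalize_intensity(sequence.frames[0].values)
    fields = []
    for frame in sequence.frames:
        vt = normalize_intensity(frame.values)
        fields.append(net.forward_pair(v0, vt))
    return fields


def center_dataset(phantoms: list, sigma_mm: float = 10.0) -> list:
    """(normalised ED volume, Gaussian centre heatmap) per phantom.

    ``phantoms`` is a list of (CineSequence, PhantomTruth) tuples."""
    data = []
    for seq, truth in phantoms:
        vol = normalize_intensity(seq.frames[0].values)
        data.append((vol, gaussian_target(truth.masks[0], sigma_mm)))
    return data


def segment_dataset(phantoms: list, max_slices_per_phantom: int | None = None
                   ) -> list:
    """(normalised 2D slice, one-hot (4, nx, ny) target) over all frames' ED/ES."""
    data = []
    for seq, truth in phantoms:
        for t in (0, truth.es_index):
            vol = normalize_intensity(seq.frames[t].values)
            onehot = truth.masks[t].one_hot()
            nz = vol.shape[2]
            ks = range(nz) if max_slices_per_phantom is None else \
                range(0, nz, max(1, nz // max_slices_per_phantom))
            for k in ks:
                data.append((vol[:, :, k], onehot[:, :, :, k]))
    return data


def motion_dataset(phantoms: list) -> list:
    """(v0, v_es, m0 one-hot, m_es one-hot) per phantom (the identity pair
    is added too, so the network learns the identity transform)."""
    data = []
    for seq, truth in phantoms:
        masks = truth.masks
        for v0, vt, m0, mt in make_pairs(
                CineSequence(seq.frames, seq.frame_times, truth.es_index), masks):
            data.append((v0, vt, m0.one_hot(), mt.one_hot()))
    return data


def save_history(path: str | Path, history: list[float]) -> None:
    """Per-epoch mean loss as a two-column CSV."""
    lines = ["epoch,loss"] + [f"{i},{v:.10g}" for i, v in enumerate(history)]
    Path(path).write_text("\n".join(lines) + "\n")
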