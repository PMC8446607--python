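"""Training losses.

* heatmap regression: mean-squared error;
* segmentation: multi-class Dice (MDC) and categorical cross-entropy (CCE);
* motion estimation: intensity (mean absolute warped-image difference),
  anatomical (segmentation loss between the reference mask and the warped
  moving mask), and a diffusion (smoothness) regulariser on the field, with
  spacing-aware gradients; combined as

      L = lambda_i * L_intensity + lambda_a * L_anatomical + lambda_s * L_smooth

  with default weights (0.01, 0.5, 0.1).

Every loss accepts plain numpy arrays (returns a float) or autodiff tensors
(returns a tensor for backpropagation).  Masks are 4-channel, one-hot or
soft; the soft-Dice relaxation uses products for intersections and sums for
sizes, and an empty class counts as perfect agreement.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn.engine import Tensor, concat, warp3d

__all__ = ["LossWeights", "mse_loss", "mdc_loss", "cce_loss", "intensity_loss",
           "anatomical_loss", "smoothness_loss", "motion_total_loss"]

_EPS_CCE = 1e-7
_EPS_DICE = 1e-7
N_CLASSES = 4


@dataclasses.dataclass(frozen=True)
class LossWeights:
    lambda_i: float = 0.01
    lambda_a: float = 0.5
    lambda_s: float = 0.1

    def __post_init__(self):
        if min(self.lambda_i, self.lambda_a, self.lambda_s) < 0:
            raise ValueError("loss weights must be non-negative")


def _prepare(*xs):
    """Wrap arrays as tensors; remember whether a tensor was passed in."""
    tensorial = any(isinstance(x, Tensor) for x in xs)
    return tensorial, [x if isinstance(x, Tensor) else Tensor(np.asarray(x))
                       for x in xs]


def _ret(tensorial: bool, out: Tensor):
    return out if tensorial else out.item()


def _channel_axis(shape: tuple[int, ...], explicit: int | None) -> int:
    if explicit is not None:
        return explicit % len(shape)
    if shape[0] == N_CLASSES:
        return 0
    if len(shape) > 1 and shape[1] == N_CLASSES:
        return 1
    raise ValueError(f"cannot locate the 4-class channel axis in shape {shape}")


def mse_loss(a, b):
    """Mean squared difference over the whole domain."""
    tens, (ta, tb) = _prepare(a, b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch {ta.shape} vs {tb.shape}")
    d = ta - tb
    return _ret(tens, (d * d).mean())


def mdc_loss(m_a, m_b, channel_axis: int | None = None):
    """Negative mean of per-class soft Dice over the 4 tissue classes.

    Perfect agreement scores -1; the per-class term for a class absent from
    both masks is 1 (no penalty for correctly absent tissue).
    """
    tens, (ta, tb) = _prepare(m_a, m_b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch {ta.shape} vs {tb.shape}")
    ax = _channel_axis(ta.shape, channel_axis)
    if ta.shape[ax] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} channels on axis {ax}")
    reduce_axes = tuple(i for i in range(ta.ndim) if i != ax)
    inter = (ta * tb).sum(axis=reduce_axes)
    sizes = ta.sum(axis=reduce_axes) + tb.sum(axis=reduce_axes)
    dice = (2.0 * inter + _EPS_DICE) / (sizes + _EPS_DICE)
    return _ret(tens, -dice.mean())


def cce_loss(m_true, m_prob, channel_axis: int | None = None):
    """Pixel-wise categorical cross-entropy, probabilities clipped at 1e-7."""
    tens, (tt, tp) = _prepare(m_true, m_prob)
    if tt.shape != tp.shape:
        raise ValueError(f"shape mismatch {tt.shape} vs {tp.shape}")
    ax = _channel_axis(tt.shape, channel_axis)
    p = tp.clip(_EPS_CCE, 1.0)
    per_pixel = -(tt * p.log()).sum(axis=ax)
    return _ret(tens, per_pixel.mean())


def _as_batched(x: Tensor, channels: int) -> Tensor:
    """Promote (X,Y,Z) / (C,X,Y,Z) to (1,C,X,Y,Z); pass 5D through."""
    if x.ndim == 3:
        return x.reshape((1, 1) + x.shape)
    if x.ndim == 4:
        if x.shape[0] != channels:
            raise ValueError(f"expected {channels} leading channels, got {x.shape}")
        return x.reshape((1,) + x.shape)
    if x.ndim == 5:
        return x
    raise ValueError(f"unsupported rank {x.ndim}")


def intensity_loss(v0, vt, u):
    """Mean absolute difference between the reference frame and the warped
    moving frame: mean_v |V0(v) - Vt(v + u(v))|."""
    tens, (t0, t1, tu) = _prepare(v0, vt, u)
    b0 = _as_batched(t0, 1)
    b1 = _as_batched(t1, 1)
    bu = _as_batched(tu, 3)
    if b0.shape != b1.shape:
        raise ValueError("frames must share a grid")
    warped = warp3d(b1, bu)
    return _ret(tens, (b0 - warped).abs().mean())


def anatomical_loss(m0, mt, u, mode: str = "mdc"):
    """Segmentation loss between the reference mask and the warped moving
    mask.  Channels are warped independently with trilinear interpolation
    (a soft mask results), then MDC (default) or CCE is applied."""
    if mode not in ("mdc", "cce"):
        raise ValueError(f"unknown anatomical mode {mode!r}")
    tens, (t0, t1, tu) = _prepare(m0, mt, u)
    b0 = _as_batched(t0, N_CLASSES)
    b1 = _as_batched(t1, N_CLASSES)
    bu = _as_batched(tu, 3)
    if b0.shape[1] != N_CLASSES or b1.shape[1] != N_CLASSES:
        raise ValueError("masks must have 4 channels")
    warped = warp3d(b1, bu)
    if mode == "mdc":
        out = mdc_loss(b0, warped, channel_axis=1)
    else:
        out = cce_loss(b0, warped, channel_axis=1)
    if isinstance(out, float):                  # inputs were all arrays
        return out
    return _ret(tens, out)


def _diff_along(u: Tensor, axis: int) -> Tensor:
    """Central differences along one spatial axis (one-sided at borders)."""
    nd = u.ndim
    ax = axis % nd

    def sl(s):
        idx = [slice(None)] * nd
        idx[ax] = s
        return tuple(idx)

    interior = (u[sl(slice(2, None))] - u[sl(slice(None, -2))]) * 0.5
    first = u[sl(slice(1, 2))] - u[sl(slice(0, 1))]
    last = u[sl(slice(-1, None))] - u[sl(slice(-2, -1))]
    return concat([first, interior, last], axis=ax)


def smoothness_loss(u, dr=(1.0, 1.0, 1.0), reduction: str = "mean"):
    """Diffusion regulariser: ||grad u(v) * dr||^2 over the domain.

    Each directional derivative (voxel differences) is multiplied by the
    matching spacing entry before squaring, so in-plane and through-plane
    gradients are weighted by the true anisotropic resolution.  ``reduction``
    is "mean" (default, scale-stable across grid sizes) or "sum".
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    tens, (tu,) = _prepare(u)
    if tu.ndim not in (4, 5) or tu.shape[-4] != 3:
        raise ValueError(f"displacement field must be (.., 3, X, Y, Z), got {tu.shape}")
    dr = np.asarray(dr, dtype=np.float64)
    total = None
    for d in range(3):
        g = _diff_along(tu, axis=tu.ndim - 3 + d) * float(dr[d])
        term = (g * g).sum()
        total = term if total is None else total + term
    if reduction == "mean":
        n_vox = int(np.prod(tu.shape)) // 3      # voxels per component set
        total = total * (1.0 / n_vox)
    return _ret(tens, total)


def motion_total_loss(v0, vt, m0, mt, u, weights: LossWeights = LossWeights(),
                      dr=(1.0, 1.0, 1.0), anatomical_mode: str = "mdc"):
    """Weighted combination of intensity, anatomical, and smoothness terms."""
    tens = any(isinstance(x, Tensor) for x in (v0, vt, m0, mt, u))
    li = intensity_loss(v0, vt, u) if weights.lambda_i else 0.0
    la = anatomical_loss(m0, mt, u, mode=anatomical_mode) if weights.lambda_a else 0.0
    ls = smoothness_loss(u, dr=dr) if weights.lambda_s else 0.0
    total = weights.lambda_i * li + weights.lambda_a * la + weights.lambda_s * ls
    if isinstance(total, (int, float)) and not tens:
        return float(total)
    return total
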