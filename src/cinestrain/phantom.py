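"""Analytic contracting/twisting left-ventricle phantom.

The phantom is an annular LV myocardium (endocardial radius ``r_endo``,
epicardial radius ``r_epi`` at end-diastole) with a bright blood pool, an
adjacent RV blob marking the septal direction, and a dark background, on an
anisotropic short-axis grid.  Through the cycle the endocardium contracts by
a peak fraction ``a`` following a smooth activation curve, the wall deforms
by per-slice (2D) incompressibility, and each slice rotates by a
slice-dependent twist.  The motion is closed form and invertible, so every
frame comes with exact ground-truth displacement, advected masks, advected
landmarks, and closed-form radial/circumferential Green-Lagrange strain:

    wall radius map      r'(r)^2 = r_endo(t)^2 + r^2 - r_endo(0)^2
    circumferential      E_cc = ((r'/r)^2 - 1) / 2
    radial               E_rr = ((dr'/dr)^2 - 1) / 2,  dr'/dr = r/r'

and the 2D incompressibility identity (1+2E_rr)(1+2E_cc) = 1 holds at
every wall radius.  Twist adds only shear in the aligned cylindrical frame.

Intensities are piecewise-constant tissue classes plus a smooth random
texture (advected with the tissue, so it provides trackable features) and
per-frame Gaussian noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import (
    CineSequence,
    DisplacementField,
    SegMask,
    Volume,
    VolumeGrid,
    LABEL_LV,
    LABEL_LVM,
    LABEL_RV,
)

__all__ = ["PhantomParams", "PhantomTruth", "activation", "analytic_motion",
           "analytic_strain", "analytic_global_strain", "render_sequence"]

# intensity levels for the tissue classes (arbitrary units in [0,1])
_INTENSITY = {0: 0.10, LABEL_RV: 0.80, LABEL_LVM: 0.45, LABEL_LV: 0.90}
_DECAY_MM = 8.0  # e-folding length of the motion taper outside the epicardium
# The incompressible wall map is extended this far past both wall boundaries
# before switching to the cavity-core / far-field forms, so the motion is
# smooth over the finite-difference stencil of every myocardium voxel.
_WALL_MARGIN_MM = 4.0


@dataclasses.dataclass
class PhantomParams:
    endo_radius_ed: float = 25.0          # mm
    epi_radius_ed: float = 35.0           # mm
    rv_offset: tuple[float, float] = (-45.0, 0.0)   # mm, septal direction
    rv_radius: float = 16.0               # mm
    contraction_fraction: float = 0.2     # peak fractional endo-radius drop
    twist_per_slice: float = 2.0          # degrees per slice at peak
    n_frames: int = 25
    cycle_ms: float = 1000.0
    es_fraction: float = 0.4
    noise_sd: float = 0.02
    texture_amp: float = 0.10
    banding: bool = False                 # optional dark-stripe artifact
    grid: VolumeGrid = dataclasses.field(
        default_factory=lambda: VolumeGrid((256, 256, 16), (1.25, 1.25, 7.0)))
    center_offset: tuple[float, float] = (0.0, 0.0)  # LV centre shift, mm
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.endo_radius_ed < self.epi_radius_ed:
            raise ValueError("need 0 < endo_radius_ed < epi_radius_ed")
        if not 0 <= self.contraction_fraction < 1:
            raise ValueError("contraction_fraction must be in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not 0 < self.es_fraction < 1:
            raise ValueError("es_fraction must be in (0, 1)")

    @classmethod
    def desk(cls, seed: int = 0, shape: tuple[int, int, int] = (64, 64, 8),
             **overrides) -> "PhantomParams":
        """Reduced-scale parameter set for CPU-sized experiments."""
        defaults = dict(
            endo_radius_ed=12.0, epi_radius_ed=18.0,
            rv_offset=(-24.0, 0.0), rv_radius=8.0,
            twist_per_slice=2.0,
            grid=VolumeGrid(shape, (1.25, 1.25, 8.0)),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def lv_center_mm(self) -> tuple[float, float]:
        g = self.grid
        return ((g.shape[0] - 1) / 2.0 * g.spacing[0] + self.center_offset[0],
                (g.shape[1] - 1) / 2.0 * g.spacing[1] + self.center_offset[1])

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * (self.cycle_ms / self.n_frames)


@dataclasses.dataclass
class PhantomTruth:
    """Exact ground truth accompanying a rendered phantom sequence."""

    params: PhantomParams
    displacements: list[DisplacementField]      # u_gt per frame, ED reference
    masks: list[SegMask]                        # advected 4-class masks
    global_err: np.ndarray                      # analytic wall-averaged E_rr(t)
    global_ecc: np.ndarray                      # analytic wall-averaged E_cc(t)
    landmarks_ed: np.ndarray                    # (n, 3) mm, mid-wall at ED
    es_index: int

    def advect_landmarks(self, t_ms: float) -> np.ndarray:
        """Exact landmark positions at time t via the analytic map."""
        return _apply_map(self.params, self.landmarks_ed, activation(t_ms, self.params))


def activation(t_ms: float, params: PhantomParams) -> float:
    """Smooth activation s(t): 0 at ED, 1 at end-systole, 0 at cycle end.

    sin^2 profile with a piecewise time warp placing the peak at
    ``es_fraction`` of the cycle.
    """
    T, es = params.cycle_ms, params.es_fraction
    if not 0 <= t_ms <= T:
        raise ValueError(f"t={t_ms} outside cycle [0, {T}]")
    if t_ms <= es * T:
        tau = 0.5 * t_ms / (es * T)
    else:
        tau = 0.5 + 0.5 * (t_ms - es * T) / (T - es * T)
    return float(np.sin(np.pi * tau) ** 2)


# ---------------------------------------------------------------------------
# The radial map and its inverse
# ---------------------------------------------------------------------------


def _map_radii(s: float, p: PhantomParams) -> tuple[float, float, float, float]:
    """Transition radii of the piecewise radial map at activation s.

    Returns (re_t, r_core, r_far, delta): deformed endo radius, inner and
    outer switch radii of the extended incompressible region, and the
    far-field displacement at r_far.
    """
    r0, r1 = p.endo_radius_ed, p.epi_radius_ed
    re_t = r0 * (1.0 - p.contraction_fraction * s)
    # smallest radius where the incompressible form is real, plus safety
    r_core = float(np.sqrt(max(r0**2 - re_t**2, 0.0)) + 1.0)
    r_core = min(r_core, 0.75 * r0)
    r_far = r1 + _WALL_MARGIN_MM
    r_far_mapped = float(np.sqrt(re_t**2 + r_far**2 - r0**2))
    return re_t, r_core, r_far, r_far_mapped - r_far


def _radius_forward(r: np.ndarray, s: float, p: PhantomParams) -> np.ndarray:
    """Map ED radius r (mm) to deformed radius r' at activation s.

    Piecewise: linear core near the axis, the 2D-incompressible form
    r'^2 = re_t^2 + r^2 - r0^2 across the wall (extended by a margin on
    both sides so the map is smooth over the wall), and an exponentially
    tapering displacement in the far field.
    """
    r = np.asarray(r, dtype=np.float64)
    r0 = p.endo_radius_ed
    re_t, r_core, r_far, delta = _map_radii(s, p)
    out = np.empty_like(r)
    core = r <= r_core
    wall = (r > r_core) & (r <= r_far)
    far = r > r_far
    core_scale = np.sqrt(re_t**2 + r_core**2 - r0**2) / r_core
    out[core] = r[core] * core_scale
    out[wall] = np.sqrt(re_t**2 + r[wall] ** 2 - r0**2)
    out[far] = r[far] + delta * np.exp(-(r[far] - r_far) / _DECAY_MM)
    return out


def _radius_inverse(rp: np.ndarray, s: float, p: PhantomParams) -> np.ndarray:
    """Invert the radius map (monotone, hence unique)."""
    rp = np.asarray(rp, dtype=np.float64)
    r0 = p.endo_radius_ed
    re_t, r_core, r_far, delta = _map_radii(s, p)
    core_scale = np.sqrt(re_t**2 + r_core**2 - r0**2) / r_core
    rp_core = r_core * core_scale
    rp_far = r_far + delta
    out = np.empty_like(rp)
    core = rp <= rp_core
    wall = (rp > rp_core) & (rp <= rp_far)
    far = rp > rp_far
    out[core] = rp[core] / core_scale
    out[wall] = np.sqrt(np.maximum(rp[wall] ** 2 - re_t**2 + r0**2, 0.0))
    # far field: solve r + delta*exp(-(r-r_far)/L) = r' by Newton (f' >= 1)
    r = rp[far] - delta
    target = rp[far]
    for _ in range(25):
        e = np.exp(-(r - r_far) / _DECAY_MM)
        f = r + delta * e - target
        fp = 1.0 - (delta / _DECAY_MM) * e
        r = r - f / fp
    out[far] = r
    return out


def _twist_weight(r: np.ndarray, p: PhantomParams) -> np.ndarray:
    # full twist out to the extended wall margin, exponential taper beyond,
    # so angular motion is smooth across the myocardium
    r_far = p.epi_radius_ed + _WALL_MARGIN_MM
    w = np.ones_like(np.asarray(r, dtype=np.float64))
    outside = r > r_far
    w[outside] = np.exp(-(r[outside] - r_far) / _DECAY_MM)
    return w


def _apply_map(p: PhantomParams, points_mm: np.ndarray, s: float) -> np.ndarray:
    """Forward map phi applied to (n, 3) points in mm (z untouched)."""
    cx, cy = p.lv_center_mm
    pts = np.asarray(points_mm, dtype=np.float64)
    if s == 0.0:
        return pts.copy()        # exact identity at zero activation
    dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    rp = _radius_forward(r, s, p)
    z_slice = pts[:, 2] / p.grid.spacing[2]
    twist = np.deg2rad(p.twist_per_slice) * z_slice * s * _twist_weight(r, p)
    theta_p = theta + twist
    out = pts.copy()
    out[:, 0] = cx + rp * np.cos(theta_p)
    out[:, 1] = cy + rp * np.sin(theta_p)
    return out


def analytic_motion(params: PhantomParams, t_ms: float) -> DisplacementField:
    """Ground-truth forward displacement u_gt on the ED grid (voxel units)."""
    s = activation(t_ms, params)
    g = params.grid
    xs = np.arange(g.shape[0]) * g.spacing[0]
    ys = np.arange(g.shape[1]) * g.spacing[1]
    zs = np.arange(g.shape[2]) * g.spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    mapped = _apply_map(params, pts, s)
    u_mm = (mapped - pts).reshape(g.shape + (3,))
    u_vox = np.moveaxis(u_mm, -1, 0) / np.asarray(g.spacing).reshape(3, 1, 1, 1)
    return DisplacementField(g, u_vox)


def analytic_strain(params: PhantomParams, t_ms: float,
                    r: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (E_rr, E_cc) at ED wall radius r (mm)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < params.endo_radius_ed - 1e-9) or np.any(r > params.epi_radius_ed + 1e-9):
        raise ValueError("radius outside the ED wall")
    s = activation(t_ms, params)
    rp = _radius_forward(r, s, params)
    e_cc = ((rp / r) ** 2 - 1.0) / 2.0
    e_rr = ((r / rp) ** 2 - 1.0) / 2.0   # dr'/dr = r/r' for the area-preserving map
    return e_rr, e_cc


def analytic_global_strain(params: PhantomParams, t_ms: float,
                           n_quad: int = 2000) -> tuple[float, float]:
    """Area-weighted wall averages of the closed-form strains.

    The weight 2*pi*r dr matches an unweighted voxel average over the ED
    annulus.
    """
    r = np.linspace(params.endo_radius_ed, params.epi_radius_ed, n_quad)
    e_rr, e_cc = analytic_strain(params, t_ms, r)
    w = r
    return (float(np.trapezoid(e_rr * w, r) / np.trapezoid(w, r)),
            float(np.trapezoid(e_cc * w, r) / np.trapezoid(w, r)))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _ed_labels(p: PhantomParams) -> np.ndarray:
    g = p.grid
    cx, cy = p.lv_center_mm
    xs = np.arange(g.shape[0]) * g.spacing[0]
    ys = np.arange(g.shape[1]) * g.spacing[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    r = np.hypot(X - cx, Y - cy)
    rv = np.hypot(X - cx - p.rv_offset[0], Y - cy - p.rv_offset[1])
    sl = np.zeros(g.shape[:2], dtype=np.int16)
    sl[rv <= p.rv_radius] = LABEL_RV
    sl[(r >= p.endo_radius_ed) & (r <= p.epi_radius_ed)] = LABEL_LVM
    sl[r < p.endo_radius_ed] = LABEL_LV
    return np.repeat(sl[:, :, None], g.shape[2], axis=2)


def _classify_ed_points(p: PhantomParams, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    """Exact ED tissue label at continuous ED coordinates."""
    cx, cy = p.lv_center_mm
    r = np.hypot(x_mm - cx, y_mm - cy)
    rv = np.hypot(x_mm - cx - p.rv_offset[0], y_mm - cy - p.rv_offset[1])
    lab = np.zeros(r.shape, dtype=np.int16)
    lab[rv <= p.rv_radius] = LABEL_RV
    lab[(r >= p.endo_radius_ed) & (r <= p.epi_radius_ed)] = LABEL_LVM
    lab[r < p.endo_radius_ed] = LABEL_LV
    return lab


def _inverse_map_grid(p: PhantomParams, s: float) -> tuple[np.ndarray, np.ndarray]:
    """ED (x, y) mm coordinates for every voxel of the deformed frame."""
    g = p.grid
    cx, cy = p.lv_center_mm
    xs = np.arange(g.shape[0]) * g.spacing[0]
    ys = np.arange(g.shape[1]) * g.spacing[1]
    zs = np.arange(g.shape[2], dtype=np.float64)  # slice index for twist
    X, Y, Zi = np.meshgrid(xs, ys, zs, indexing="ij")
    dx, dy = X - cx, Y - cy
    rp = np.hypot(dx, dy)
    theta_p = np.arctan2(dy, dx)
    r = _radius_inverse(rp.ravel(), s, p).reshape(rp.shape)
    twist = np.deg2rad(p.twist_per_slice) * Zi * s * _twist_weight(r, p)
    theta = theta_p - twist
    return cx + r * np.cos(theta), cy + r * np.sin(theta)


def render_sequence(params: PhantomParams) -> tuple[CineSequence, PhantomTruth]:
    """Render the cine sequence and its exact ground truth.

    Frame t is V_t(x) = V_0(phi_t^-1(x)), so the motion-estimation
    convention V_0(v) = V_t(v + u_gt(v)) holds exactly (up to noise and the
    texture interpolation).  Masks are advected with exact analytic
    classification at the inverse-mapped coordinates (no interpolation).
    """
    p = params
    g = p.grid
    rng = np.random.default_rng(p.seed)

    # smooth tissue texture on the ED grid, advected with the motion
    texture = rng.standard_normal(g.shape)
    texture = ndimage.gaussian_filter(texture, sigma=(2.5, 2.5, 0.5))
    texture *= p.texture_amp / max(texture.std(), 1e-12)

    ed_labels = _ed_labels(p)
    base_ed = np.vectorize(_INTENSITY.get)(ed_labels).astype(np.float64)

    frames: list[Volume] = []
    masks: list[SegMask] = []
    fields: list[DisplacementField] = []
    times = p.frame_times
    for t in times:
        s = activation(float(t), p)
        is_static = p.contraction_fraction == 0.0 and p.twist_per_slice == 0.0
        if s == 0.0 or is_static:
            lab = ed_labels.copy()
            base = base_ed
            tex = texture
        else:
            ex, ey = _inverse_map_grid(p, s)
            lab = _classify_ed_points(p, ex, ey)
            base = np.vectorize(_INTENSITY.get)(lab).astype(np.float64)
            # sample the ED texture at the inverse-mapped position
            coords = np.stack([ex / g.spacing[0], ey / g.spacing[1],
                               np.broadcast_to(np.arange(g.shape[2], dtype=np.float64),
                                               g.shape)])
            tex = ndimage.map_coordinates(texture, coords, order=1, mode="nearest")
        img = base + tex
        if p.banding:
            img = img.copy()
            stripe = slice(g.shape[1] // 3, g.shape[1] // 3 + max(2, g.shape[1] // 16))
            img[:, stripe, :] *= 0.4
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, g.shape)
        frames.append(Volume(g, img))
        masks.append(SegMask(g, lab))
        fields.append(analytic_motion(p, float(t)))

    # analytic global strain curves
    e_rr = np.empty(p.n_frames)
    e_cc = np.empty(p.n_frames)
    for i, t in enumerate(times):
        e_rr[i], e_cc[i] = analytic_global_strain(p, float(t), n_quad=400)

    # mid-wall landmark ring on every slice at ED
    cx, cy = p.lv_center_mm
    r_mid = 0.5 * (p.endo_radius_ed + p.epi_radius_ed)
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    lms = []
    for k in range(g.shape[2]):
        for ang in angles:
            lms.append([cx + r_mid * np.cos(ang), cy + r_mid * np.sin(ang),
                        k * g.spacing[2]])
    landmarks = np.array(lms)

    es_index = int(np.argmin(np.abs(times - p.es_fraction * p.cycle_ms)))
    seq = CineSequence(frames, times, es_index=es_index)
    truth = PhantomTruth(p, fields, masks, e_rr, e_cc, landmarks, es_index)
    return seq, truth
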