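"""Green-Lagrange strain analysis in cardiac cylindrical coordinates.

From a Lagrangian displacement field u(t) defined on the end-diastolic
(ED) reference grid, the engine computes

    E(t) = (grad u + grad u^T + grad u^T grad u) / 2,

projects it onto per-voxel radial/circumferential/longitudinal unit vectors
derived from the segmentation (per-slice LV centre, septal direction from
the RV centroid), averages over the ED myocardium for global strain or over
the 16 AHA segments for regional strain, interpolates the curves to a 1 ms
grid, differentiates for strain rate, and extracts the scalar parameters
ESS (end-systolic strain), SRs (peak systolic strain rate) and SRe (peak
early-diastolic strain rate).

Conventions: strain is computed on the ED grid from the forward field u_t
and averaged over the ED myocardium mask; u at t = 0 is taken as zero so
the curves start at exactly 0.  Strains are reported in percent; strain
rate in 1/s, signed by the value at the absolute peak.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grids import DisplacementField, SegMask, LABEL_LV, LABEL_LVM, LABEL_RV

__all__ = ["CardiacCoordinateSystem", "CylStrainField", "StrainCurveSet",
           "PolarMap", "displacement_gradient", "green_lagrange",
           "define_cardiac_cs", "cylindrical_project", "global_strain",
           "interpolate_and_rate", "extract_params", "polar_map", "detect_es",
           "strain_curves_from_fields", "AHA_SEGMENT_NAMES"]


@dataclasses.dataclass
class CardiacCoordinateSystem:
    """Per-voxel cylindrical frame about the LV long axis (the grid z)."""

    center_xy: np.ndarray          # (nz, 2) per-slice LV centre, voxel coords
    radial: np.ndarray             # (3, nx, ny, nz) unit vectors
    circumferential: np.ndarray    # (3, nx, ny, nz)
    longitudinal: np.ndarray       # (3, nx, ny, nz), constant (0,0,1)
    septal_angle: np.ndarray | None  # (nz,) rad, direction of RV centroid
    defined: np.ndarray            # (nx, ny, nz) bool, False on the axis


@dataclasses.dataclass
class CylStrainField:
    """Per-voxel cylindrical strain components (unitless)."""

    e_rr: np.ndarray
    e_cc: np.ndarray
    e_zz: np.ndarray
    e_rc: np.ndarray
    e_rz: np.ndarray
    e_cz: np.ndarray
    defined: np.ndarray


@dataclasses.dataclass
class StrainCurveSet:
    """Millisecond-resolved global strain and strain-rate curves."""

    time_ms: np.ndarray
    strain: dict[str, np.ndarray]        # component -> unitless curve
    strain_rate: dict[str, np.ndarray]   # component -> 1/s curve
    es_time_ms: float
    params: dict[str, dict[str, float]]  # component -> {ESS_percent, SRs, SRe}


AHA_SEGMENT_NAMES = [
    "basal anterior", "basal anteroseptal", "basal inferoseptal",
    "basal inferior", "basal inferolateral", "basal anterolateral",
    "mid anterior", "mid anteroseptal", "mid inferoseptal",
    "mid inferior", "mid inferolateral", "mid anterolateral",
    "apical anterior", "apical septal", "apical inferior", "apical lateral",
]


@dataclasses.dataclass
class PolarMap:
    """16-segment AHA polar map: 6 basal, 6 mid, 4 apical."""

    values: np.ndarray        # (16,)
    voxel_counts: np.ndarray  # (16,) int


# ---------------------------------------------------------------------------
# Tensor algebra
# ---------------------------------------------------------------------------


def displacement_gradient(field: DisplacementField) -> np.ndarray:
    """Per-voxel gradient of physical displacement wrt physical coordinates.

    Returns (nx, ny, nz, 3, 3) with entry [..., i, j] = d u_i / d x_j (mm/mm).
    Central differences in the interior, one-sided at array borders.
    """
    g = field.grid
    if any(s < 3 for s in g.shape):
        raise ValueError("need at least 3 voxels per axis for central differences")
    u_mm = field.to_mm()
    grad = np.empty(g.shape + (3, 3))
    for i in range(3):
        gx, gy, gz = np.gradient(u_mm[i], g.spacing[0], g.spacing[1], g.spacing[2])
        grad[..., i, 0], grad[..., i, 1], grad[..., i, 2] = gx, gy, gz
    return grad


def green_lagrange(grad_u: np.ndarray) -> np.ndarray:
    """E = (grad u + grad u^T + grad u^T grad u) / 2, symmetric."""
    gt = np.swapaxes(grad_u, -1, -2)
    return 0.5 * (grad_u + gt + np.einsum("...ki,...kj->...ij", grad_u, grad_u))


# ---------------------------------------------------------------------------
# Cardiac coordinate system
# ---------------------------------------------------------------------------


def define_cardiac_cs(mask: SegMask) -> CardiacCoordinateSystem:
    """Build the cylindrical frame from a 4-class segmentation.

    The per-slice LV centre is the centroid of myocardium + cavity; the
    septal angle per slice is the direction of the RV centroid from the LV
    centre (unavailable slices inherit their nearest defined neighbour).
    """
    labels = mask.labels
    nx, ny, nz = labels.shape
    lv = (labels == LABEL_LVM) | (labels == LABEL_LV)
    if not lv.any():
        raise ValueError("mask contains no LV myocardium or cavity")

    center = np.full((nz, 2), np.nan)
    septal = np.full(nz, np.nan)
    for k in range(nz):
        sl = lv[:, :, k]
        if sl.any():
            xs, ys = np.nonzero(sl)
            center[k] = (xs.mean(), ys.mean())
            rv = labels[:, :, k] == LABEL_RV
            if rv.any():
                rx, ry = np.nonzero(rv)
                septal[k] = np.arctan2(ry.mean() - center[k, 1],
                                       rx.mean() - center[k, 0])
    # fill empty slices from the nearest defined slice
    defined_slices = np.nonzero(~np.isnan(center[:, 0]))[0]
    for k in range(nz):
        if np.isnan(center[k, 0]):
            near = defined_slices[np.argmin(np.abs(defined_slices - k))]
            center[k] = center[near]
    has_rv = not np.all(np.isnan(septal))
    if has_rv:
        rv_slices = np.nonzero(~np.isnan(septal))[0]
        for k in range(nz):
            if np.isnan(septal[k]):
                septal[k] = septal[rv_slices[np.argmin(np.abs(rv_slices - k))]]

    xi = np.arange(nx)[:, None, None]
    yi = np.arange(ny)[None, :, None]
    dx = xi - center[:, 0][None, None, :]
    dy = yi - center[:, 1][None, None, :]
    rho = np.hypot(dx, dy)
    ok = rho > 1e-9
    safe = np.where(ok, rho, 1.0)
    radial = np.zeros((3, nx, ny, nz))
    radial[0], radial[1] = dx / safe, dy / safe
    circ = np.zeros((3, nx, ny, nz))
    circ[0], circ[1] = -radial[1], radial[0]
    longit = np.zeros((3, nx, ny, nz))
    longit[2] = 1.0
    return CardiacCoordinateSystem(center, radial, circ, longit,
                                   septal if has_rv else None, ok)


def cylindrical_project(e_tensor: np.ndarray,
                        cs: CardiacCoordinateSystem) -> CylStrainField:
    """Project the Cartesian strain tensor onto the cylindrical frame."""
    r = np.moveaxis(cs.radial, 0, -1)
    c = np.moveaxis(cs.circumferential, 0, -1)
    z = np.moveaxis(cs.longitudinal, 0, -1)

    def proj(a, b):
        return np.einsum("...i,...ij,...j->...", a, e_tensor, b)

    return CylStrainField(
        e_rr=proj(r, r), e_cc=proj(c, c), e_zz=proj(z, z),
        e_rc=proj(r, c), e_rz=proj(r, z), e_cz=proj(c, z),
        defined=cs.defined.copy())


def global_strain(cyl: CylStrainField, lvm_mask: np.ndarray,
                  component: str = "e_cc") -> float:
    """Unweighted mean over myocardium voxels, in percent."""
    sel = np.asarray(lvm_mask, dtype=bool) & cyl.defined
    if not sel.any():
        raise ValueError("empty myocardium mask")
    return float(np.mean(getattr(cyl, component)[sel])) * 100.0


# ---------------------------------------------------------------------------
# Curves, rates, scalar parameters
# ---------------------------------------------------------------------------


def interpolate_and_rate(values: np.ndarray, frame_times: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear interpolation to a 1 ms grid and strain rate in 1/s.

    Returns (time_ms, strain_ms, rate_per_s).  The rate uses central
    differences on the millisecond grid (one-sided at the ends).
    """
    values = np.asarray(values, dtype=np.float64)
    frame_times = np.asarray(frame_times, dtype=np.float64)
    if len(values) < 3:
        raise ValueError("need at least 3 frames")
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    t_ms = np.arange(np.ceil(frame_times[0]), np.floor(frame_times[-1]) + 1)
    strain_ms = np.interp(t_ms, frame_times, values)
    rate = np.gradient(strain_ms, t_ms) * 1000.0   # per ms -> per s
    return t_ms, strain_ms, rate


def extract_params(t_ms: np.ndarray, strain_ms: np.ndarray, rate: np.ndarray,
                   es_time_ms: float) -> dict[str, float]:
    """ESS (percent), SRs and SRe (1/s, signed at the absolute peak)."""
    if not t_ms[0] <= es_time_ms <= t_ms[-1]:
        raise ValueError(f"es_time {es_time_ms} outside curve range")
    ess = float(np.interp(es_time_ms, t_ms, strain_ms)) * 100.0
    sys_sel = t_ms <= es_time_ms
    dia_sel = t_ms > es_time_ms
    if not sys_sel.any() or not dia_sel.any():
        raise ValueError("ES time leaves an empty systolic or diastolic window")
    sr_sys = rate[sys_sel][np.argmax(np.abs(rate[sys_sel]))]
    sr_dia = rate[dia_sel][np.argmax(np.abs(rate[dia_sel]))]
    return {"ESS_percent": ess, "SRs_per_s": float(sr_sys),
            "SRe_per_s": float(sr_dia)}


def detect_es(masks: list[SegMask]) -> int:
    """ES index = frame of minimum LV cavity volume (ties -> earliest)."""
    volumes = []
    for m in masks:
        if not (m.labels == LABEL_LV).any():
            raise ValueError("a frame mask has no LV cavity label")
        volumes.append(int(np.sum(m.labels == LABEL_LV)))
    return int(np.argmin(volumes))


# ---------------------------------------------------------------------------
# AHA polar map
# ---------------------------------------------------------------------------


def polar_map(cyl: CylStrainField, mask: SegMask,
              cs: CardiacCoordinateSystem, component: str = "e_cc") -> PolarMap:
    """16-segment regional averages (percent).

    Slices containing myocardium are split along z into basal/mid/apical
    thirds (remainder slices go to basal, then mid).  Angular sectors are
    measured from the anterior RV insertion, taken as the septal direction
    rotated by +90 deg: six 60-deg sectors on basal and mid rings, four
    90-deg sectors apically.
    """
    if cs.septal_angle is None:
        raise ValueError("polar map needs the RV label for orientation")
    labels = mask.labels
    lvm = labels == LABEL_LVM
    slices = np.nonzero(lvm.any(axis=(0, 1)))[0]
    if slices.size == 0:
        raise ValueError("no myocardium in mask")
    n = slices.size
    base = n // 3 + (1 if n % 3 >= 1 else 0)
    mid = n // 3 + (1 if n % 3 >= 2 else 0)
    ring_of_slice = {}
    for i, k in enumerate(slices):
        ring_of_slice[k] = 0 if i < base else (1 if i < base + mid else 2)

    field = getattr(cyl, component)
    values = np.zeros(16)
    counts = np.zeros(16, dtype=np.int64)
    sums = np.zeros(16)
    nx, ny, _ = labels.shape
    xi = np.arange(nx)[:, None]
    yi = np.arange(ny)[None, :]
    for k in slices:
        sel = lvm[:, :, k] & cyl.defined[:, :, k]
        if not sel.any():
            continue
        ang = np.arctan2(yi - cs.center_xy[k, 1], xi - cs.center_xy[k, 0])
        ref = cs.septal_angle[k] + np.pi / 2.0      # anterior RV insertion
        rel = np.mod(ang - ref, 2 * np.pi)
        ring = ring_of_slice[k]
        if ring < 2:
            sector = np.minimum((rel / (np.pi / 3.0)).astype(int), 5)
            seg = ring * 6 + sector
        else:
            sector = np.minimum((rel / (np.pi / 2.0)).astype(int), 3)
            seg = 12 + sector
        for s in np.unique(seg[sel]):
            pick = sel & (seg == s)
            sums[s] += field[:, :, k][pick].sum()
            counts[s] += int(pick.sum())
    nonzero = counts > 0
    values[nonzero] = sums[nonzero] / counts[nonzero] * 100.0
    return PolarMap(values, counts)


# ---------------------------------------------------------------------------
# End-to-end curves from per-frame displacement fields
# ---------------------------------------------------------------------------


def strain_curves_from_fields(fields: list[DisplacementField],
                              ed_mask: SegMask, frame_times: np.ndarray,
                              es_index: int,
                              components: tuple[str, ...] = ("e_rr", "e_cc"),
                              ) -> StrainCurveSet:
    """Global strain/strain-rate curves from per-frame motion estimates.

    The field at t = 0 is forced to zero (ED is the strain reference), the
    per-frame global values are interpolated to 1 ms, and scalar parameters
    are extracted at the ES time.
    """
    cs = define_cardiac_cs(ed_mask)
    lvm = ed_mask.labels == LABEL_LVM
    per_frame = {c: np.zeros(len(fields)) for c in components}
    for i, f in enumerate(fields):
        if i == 0:
            continue
        grad = displacement_gradient(f)
        cyl = cylindrical_project(green_lagrange(grad), cs)
        for c in components:
            per_frame[c][i] = global_strain(cyl, lvm, component=c) / 100.0

    es_time = float(frame_times[es_index])
    strain, rate, params = {}, {}, {}
    t_ms = None
    for c in components:
        t_ms, s_ms, r = interpolate_and_rate(per_frame[c], frame_times)
        strain[c], rate[c] = s_ms, r
        params[c] = extract_params(t_ms, s_ms, r, es_time)
    return StrainCurveSet(t_ms, strain, rate, es_time, params)
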