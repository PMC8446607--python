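"""Evaluation statistics: overlap, distances, volumetrics, landmark errors,
and test-retest repeatability (Bland-Altman, ICC, relative changes).

The landmark machinery mirrors a tagging-MRI validation protocol: reference
landmark positions at end-diastole are deformed by the estimated motion
field and compared, in-plane and at end-systole, against manually tracked
positions from two observers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.stats import f as f_dist

from .grids import DisplacementField, SegMask, LABEL_LV, LABEL_LVM

__all__ = ["LandmarkTrack", "dice", "hausdorff", "volumetrics", "epe",
           "deform_landmarks", "aepe", "bland_altman", "icc_a1", "rc_arc"]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclasses.dataclass
class LandmarkTrack:
    """One observer's manual track for one subject: (n_frames, n_points, 2|3) mm."""

    subject: str
    observer: int
    positions_mm: np.ndarray       # per-frame landmark positions
    reference_mm: np.ndarray       # ED positions (n_points, 3)


# ---------------------------------------------------------------------------
# Segmentation agreement
# ---------------------------------------------------------------------------


def dice(mask_a: SegMask | np.ndarray, mask_b: SegMask | np.ndarray,
         label: int) -> float:
    """Dice similarity 2|A&B| / (|A|+|B|); both-empty convention: 1."""
    a = (mask_a.labels if isinstance(mask_a, SegMask) else np.asarray(mask_a)) == label
    b = (mask_b.labels if isinstance(mask_b, SegMask) else np.asarray(mask_b)) == label
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _boundary(binary: np.ndarray) -> np.ndarray:
    return binary & ~ndimage.binary_erosion(binary)


def hausdorff(mask_a: SegMask | np.ndarray, mask_b: SegMask | np.ndarray,
              label: int, spacing: tuple[float, ...] | None = None) -> float:
    """Symmetric Hausdorff distance between label boundaries, in mm."""
    if isinstance(mask_a, SegMask):
        spacing = mask_a.grid.spacing
        a, b = mask_a.labels == label, mask_b.labels == label
    else:
        a, b = np.asarray(mask_a) == label, np.asarray(mask_b) == label
        if spacing is None:
            spacing = (1.0,) * a.ndim
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance needs both label sets non-empty")
    sp = np.asarray(spacing, dtype=np.float64)
    pa = np.argwhere(_boundary(a)) * sp
    pb = np.argwhere(_boundary(b)) * sp
    from scipy.spatial import cKDTree

    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def volumetrics(mask_ed: SegMask, mask_es: SegMask) -> dict[str, float]:
    """EDV/ESV (mL), ejection fraction (%), and LV mass (g, density 1.05)."""
    edv = mask_ed.volume_ml(LABEL_LV)
    esv = mask_es.volume_ml(LABEL_LV)
    if edv <= 0:
        raise ValueError("ED cavity volume is zero")
    lvm_ml = mask_ed.volume_ml(LABEL_LVM)
    return {
        "EDV_ml": edv,
        "ESV_ml": esv,
        "EF_percent": (edv - esv) / edv * 100.0,
        "LVM_g": lvm_ml * MYOCARDIAL_DENSITY_G_PER_ML,
    }


# ---------------------------------------------------------------------------
# Landmark end-point error
# ---------------------------------------------------------------------------


def epe(p: np.ndarray, p_prime: np.ndarray) -> float:
    """In-plane Euclidean end-point error (mm): only x, y enter."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(p_prime, dtype=np.float64)
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def deform_landmarks(p0_mm: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Deform ED landmarks by the motion field.

    The field (voxel units) is sampled at each landmark position by
    trilinear interpolation, converted to mm via the grid spacing, and its
    in-plane components added to the ED position (z kept fixed, matching
    the in-plane error definition).
    """
    g = field.grid
    pts = np.atleast_2d(np.asarray(p0_mm, dtype=np.float64))
    vox = pts / np.asarray(g.spacing)
    if np.any(vox < -0.5) or np.any(vox > np.asarray(g.shape) - 0.5):
        raise ValueError("landmark outside the grid")
    coords = vox.T                     # (3, n)
    out = pts.copy()
    for c in range(2):
        u_c = ndimage.map_coordinates(field.components[c], coords, order=1,
                                      mode="nearest")
        out[:, c] += u_c * g.spacing[c]
    return out


def aepe(tracks: list[LandmarkTrack], fields: dict[str, DisplacementField],
         es_indices: dict[str, int]) -> float:
    """Average end-point error (mm) at end-systole over subjects x observers."""
    errors = []
    for tr in tracks:
        if tr.subject not in fields:
            raise ValueError(f"no motion field for subject {tr.subject}")
        es = es_indices[tr.subject]
        deformed = deform_landmarks(tr.reference_mm, fields[tr.subject])
        manual = tr.positions_mm[es]
        errors.append(np.mean([epe(m, d) for m, d in zip(manual, deformed)]))
    if not errors:
        raise ValueError("no landmark tracks")
    return float(np.mean(errors))


# ---------------------------------------------------------------------------
# Repeatability statistics
# ---------------------------------------------------------------------------


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Bias = mean(x - y); precision = SD of differences (n-1 denominator)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired samples with n >= 2")
    d = x - y
    return float(d.mean()), float(d.std(ddof=1))


def icc_a1(table: np.ndarray, alpha: float = 0.05
           ) -> tuple[float, tuple[float, float]]:
    """ICC(A,1): single-rating, absolute-agreement, two-way model.

    ``table`` is (n_subjects, k_raters).  Returns the coefficient and the
    F-based (1 - alpha) confidence interval.
    """
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need an (n >= 3) x (k >= 2) table")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-30:
        raise ValueError("ICC undefined: no variance in the table")
    icc = (msr - mse) / denom

    # McGraw-Wong confidence interval
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = 1.0
    return float(icc), (float(lower), float(upper))


def rc_arc(x1: np.ndarray, x2: np.ndarray) -> dict[str, float]:
    """Relative change and absolute relative change (%), acquisition 1 as
    reference; summaries are mean and SD across subjects."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if np.any(x1 == 0):
        raise ValueError("zero reference value")
    rc = (x2 - x1) / x1 * 100.0
    arc = np.abs(rc)
    return {
        "RC_percent": rc,
        "aRC_percent": arc,
        "RC_mean": float(rc.mean()),
        "RC_sd": float(rc.std(ddof=1)) if rc.size > 1 else 0.0,
        "aRC_mean": float(arc.mean()),
        "aRC_sd": float(arc.std(ddof=1)) if arc.size > 1 else 0.0,
    }
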