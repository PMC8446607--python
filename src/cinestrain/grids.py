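"""Spatial data model and NIfTI input/output.

All arrays in this package are indexed ``(x, y, z)``, 0-based, with x/y the
in-plane axes and z the through-plane (slice) axis.  Displacement fields
store their three channels in the same order and in *voxel units* of the
grid they live on; physical displacement in mm is obtained by multiplying
each component with the corresponding spacing entry.

The standard workspace for whole-image networks is a 256 x 256 x 16 grid
with 1.25 x 1.25 mm in-plane spacing (slice thickness is kept from the
input data), and the cropped working grid for segmentation/motion is half
the in-plane size, 128 x 128 x 16.  Both sizes are parameters so that
reduced desk-scale grids can be used for testing and simulation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "Volume",
    "SegMask",
    "DisplacementField",
    "CineSequence",
    "WORKSPACE_SHAPE",
    "WORKSPACE_INPLANE_SPACING",
    "CROP_SHAPE",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_displacement",
    "write_displacement",
    "read_cine",
    "resample_to_workspace",
    "crop_around_center",
    "paste_back",
    "load_frame_times",
    "normalize_intensity",
]

WORKSPACE_SHAPE = (256, 256, 16)
WORKSPACE_INPLANE_SPACING = (1.25, 1.25)
CROP_SHAPE = (128, 128, 16)

LABEL_BACKGROUND = 0
LABEL_RV = 1
LABEL_LVM = 2
LABEL_LV = 3
N_CLASSES = 4


class FormatError(ValueError):
    """Raised when an input file or array violates the format contract."""


@dataclasses.dataclass(frozen=True)
class VolumeGrid:
    """Regular voxel grid: shape (nx, ny, nz), spacing dr in mm, origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3:
            raise FormatError(f"grid shape must be 3D, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"grid spacing must be positive, got {self.spacing}")
        if self.shape[2] < 2:
            raise FormatError("grid must have at least 2 slices")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, atol=tol
        )


@dataclasses.dataclass
class Volume:
    """Scalar intensity volume on a grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise FormatError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")


@dataclasses.dataclass
class SegMask:
    """4-class label volume: 0=background, 1=RV, 2=LVM, 3=LV cavity."""

    grid: VolumeGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise FormatError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        self.labels = self.labels.astype(np.int16)
        present = set(np.unique(self.labels).tolist())
        if not present <= {0, 1, 2, 3}:
            raise FormatError(f"labels outside {{0,1,2,3}}: {sorted(present)}")

    def one_hot(self) -> np.ndarray:
        """(4, nx, ny, nz) one-hot expansion; channels sum to 1 per voxel."""
        out = np.zeros((N_CLASSES,) + self.labels.shape, dtype=np.float64)
        for k in range(N_CLASSES):
            out[k] = self.labels == k
        return out

    def volume_ml(self, label: int) -> float:
        """Volume of one label in mL (1 mL = 1000 mm^3)."""
        return float(np.sum(self.labels == label)) * self.grid.voxel_volume_mm3 / 1000.0


@dataclasses.dataclass
class DisplacementField:
    """Per-voxel 3-component motion, stored as (3, nx, ny, nz) in voxel units."""

    grid: VolumeGrid
    components: np.ndarray

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.shape != (3,) + self.grid.shape:
            raise FormatError(
                f"components shape {self.components.shape} != (3,)+{self.grid.shape}"
            )
        if not np.all(np.isfinite(self.components)):
            raise FormatError("displacement field contains non-finite values")

    def to_mm(self) -> np.ndarray:
        """Physical displacement (mm): component times the matching spacing."""
        dr = np.asarray(self.grid.spacing).reshape(3, 1, 1, 1)
        return self.components * dr

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "DisplacementField":
        return cls(grid, np.zeros((3,) + grid.shape))


@dataclasses.dataclass
class CineSequence:
    """Ordered cine frames on a common grid with per-frame times in ms.

    Frame 0 is end-diastole (ED) by convention; ``es_index`` may be unset
    and recovered later from segmentation (minimum cavity volume).
    """

    frames: list[Volume]
    frame_times: np.ndarray
    es_index: int | None = None

    def __post_init__(self):
        if not self.frames:
            raise FormatError("cine sequence needs at least one frame")
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if len(self.frame_times) != len(self.frames):
            raise FormatError(
                f"{len(self.frame_times)} frame times for {len(self.frames)} frames"
            )
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise FormatError("frame times must be strictly increasing")
        g0 = self.frames[0].grid
        for f in self.frames[1:]:
            if not f.grid.same_geometry(g0):
                raise FormatError("all cine frames must share one grid")

    @property
    def ed_index(self) -> int:
        return 0

    @property
    def grid(self) -> VolumeGrid:
        return self.frames[0].grid

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# NIfTI IO.  Internal dialect: data stored in (x, y, z[, t/channel]) order,
# spacing in pixdim, origin in the affine translation.  Displacement fields
# are 4D with 3 volumes along the 4th dimension.
# ---------------------------------------------------------------------------


def _grid_from_img(img) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"non-positive spacing in header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms), origin)


def _affine(grid: VolumeGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def read_volume(path: str | Path, frame: int | None = None) -> Volume:
    """Read a 3D NIfTI volume (or one frame of a 4D file)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if frame is None:
            raise FormatError(f"{path} is 4D; pass frame index")
        data = data[..., frame]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D payload, got {data.ndim}D")
    return Volume(_grid_from_img(img), np.asarray(data, dtype=np.float64))


def write_volume(path: str | Path, volume: Volume) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.grid))
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, frame: int | None = None) -> SegMask:
    vol = read_volume(path, frame=frame)
    return SegMask(vol.grid, np.rint(vol.values).astype(np.int16))


def write_mask(path: str | Path, mask: SegMask) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.grid))
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def write_displacement(path: str | Path, field: DisplacementField) -> None:
    # 4D NIfTI with the 3 motion channels along the 4th dimension.
    data = np.moveaxis(field.components, 0, -1)
    img = nib.Nifti1Image(data, _affine(field.grid))
    img.header["descrip"] = b"displacement xyz, voxel units"
    nib.save(img, str(path))


def read_displacement(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: displacement NIfTI must be 4D with 3 volumes")
    return DisplacementField(_grid_from_img(img), np.moveaxis(data, -1, 0))


def read_cine(path: str | Path, frame_times: np.ndarray | None = None,
              cycle_ms: float | None = None) -> CineSequence:
    """Read a 4D cine NIfTI (one frame per 4th-dim index)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: cine NIfTI must be 4D")
    grid = _grid_from_img(img)
    frames = [Volume(grid, data[..., t].astype(np.float64))
              for t in range(data.shape[-1])]
    if frame_times is None:
        n = len(frames)
        cycle = 1000.0 if cycle_ms is None else float(cycle_ms)
        frame_times = np.arange(n) * (cycle / n)
    return CineSequence(frames, frame_times)


# ---------------------------------------------------------------------------
# Resampling and cropping
# ---------------------------------------------------------------------------


def resample_to_workspace(obj: Volume | SegMask,
                          target_shape: tuple[int, int, int] = WORKSPACE_SHAPE,
                          inplane_spacing: tuple[float, float] = WORKSPACE_INPLANE_SPACING,
                          ) -> Volume | SegMask:
    """Resample onto the workspace grid (default 256x256x16 at 1.25 mm in-plane).

    Intensity volumes use trilinear interpolation; masks use nearest
    neighbour, so no new labels are created.  The physical field of view is
    centred: the workspace is laid symmetrically around the input centre.
    Through-plane, the nz slices are spread over the input z-extent.
    """
    grid = obj.grid
    if any(s < 2 for s in grid.shape):
        raise FormatError(f"degenerate input grid {grid.shape}")
    is_mask = isinstance(obj, SegMask)
    data = obj.labels.astype(np.float64) if is_mask else obj.values

    tgt_shape = tuple(int(s) for s in target_shape)
    # target spacing: fixed in-plane, z chosen to cover the same physical extent
    z_extent = grid.spacing[2] * grid.shape[2]
    tgt_spacing = (float(inplane_spacing[0]), float(inplane_spacing[1]),
                   z_extent / tgt_shape[2])

    # physical centre of the input volume (voxel-centre convention)
    centre_phys = [(grid.shape[i] - 1) / 2.0 * grid.spacing[i] for i in range(3)]
    # source voxel coordinate for each target voxel
    coords = []
    for i in range(3):
        tgt_idx = np.arange(tgt_shape[i], dtype=np.float64)
        phys = (tgt_idx - (tgt_shape[i] - 1) / 2.0) * tgt_spacing[i] + centre_phys[i]
        coords.append(phys / grid.spacing[i])
    cx, cy, cz = np.meshgrid(*coords, indexing="ij")
    sample = np.stack([cx, cy, cz])

    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(data, sample, order=order, mode="nearest")
    tgt_grid = VolumeGrid(tgt_shape, tgt_spacing)
    if is_mask:
        return SegMask(tgt_grid, np.rint(out).astype(np.int16))
    return Volume(tgt_grid, out)


@dataclasses.dataclass(frozen=True)
class CropWindow:
    """Inverse mapping of a crop: source grid and in-plane start offsets."""

    source_grid: VolumeGrid
    start: tuple[int, int]
    crop_shape: tuple[int, int, int]


def crop_around_center(obj: Volume | SegMask, center_voxel: tuple[int, int],
                       crop_shape: tuple[int, int, int] | None = None,
                       ) -> tuple[Volume | SegMask, CropWindow]:
    """In-plane crop so that ``center_voxel`` maps to the window centre.

    The output is ``crop_shape`` (default: half the in-plane workspace size,
    all slices), zero-padded (intensity) or background-padded (labels) where
    the window extends past the border.  The returned :class:`CropWindow`
    records how to paste results back.
    """
    grid = obj.grid
    cx, cy = int(center_voxel[0]), int(center_voxel[1])
    if not (0 <= cx < grid.shape[0] and 0 <= cy < grid.shape[1]):
        raise FormatError(f"crop centre {center_voxel} outside grid {grid.shape}")
    if crop_shape is None:
        crop_shape = (grid.shape[0] // 2, grid.shape[1] // 2, grid.shape[2])
    w, h, nz = crop_shape
    if nz != grid.shape[2]:
        raise FormatError("crop keeps all slices; crop_shape[2] must equal nz")
    is_mask = isinstance(obj, SegMask)
    data = obj.labels if is_mask else obj.values
    out = np.zeros((w, h, nz), dtype=data.dtype)

    x0, y0 = cx - w // 2, cy - h // 2
    sx0, sx1 = max(x0, 0), min(x0 + w, grid.shape[0])
    sy0, sy1 = max(y0, 0), min(y0 + h, grid.shape[1])
    if sx0 < sx1 and sy0 < sy1:
        out[sx0 - x0:sx1 - x0, sy0 - y0:sy1 - y0, :] = data[sx0:sx1, sy0:sy1, :]

    new_grid = VolumeGrid(
        (w, h, nz), grid.spacing,
        (grid.origin[0] + x0 * grid.spacing[0],
         grid.origin[1] + y0 * grid.spacing[1], grid.origin[2]))
    window = CropWindow(grid, (x0, y0), (w, h, nz))
    if is_mask:
        return SegMask(new_grid, out), window
    return Volume(new_grid, out), window


def paste_back(obj: Volume | SegMask, window: CropWindow,
               background: Volume | SegMask | None = None) -> Volume | SegMask:
    """Place a cropped result back onto the source grid.

    The complement of the window is taken from ``background`` if given,
    otherwise zero/background-filled.
    """
    is_mask = isinstance(obj, SegMask)
    src = window.source_grid
    if background is not None:
        data = (background.labels if is_mask else background.values).copy()
    else:
        data = np.zeros(src.shape, dtype=np.int16 if is_mask else np.float64)
    x0, y0 = window.start
    w, h, nz = window.crop_shape
    sx0, sx1 = max(x0, 0), min(x0 + w, src.shape[0])
    sy0, sy1 = max(y0, 0), min(y0 + h, src.shape[1])
    crop_data = obj.labels if is_mask else obj.values
    if sx0 < sx1 and sy0 < sy1:
        data[sx0:sx1, sy0:sy1, :] = crop_data[sx0 - x0:sx1 - x0, sy0 - y0:sy1 - y0, :]
    if is_mask:
        return SegMask(src, data)
    return Volume(src, data)


# ---------------------------------------------------------------------------
# Frame times
# ---------------------------------------------------------------------------


def load_frame_times(source: str | Path | None, n_frames: int,
                     cycle_ms: float | None = None) -> np.ndarray:
    """Per-frame acquisition times in ms.

    ``source`` may be a plain-text sidecar (one value per line, or one
    comma-separated line) or a DICOM series directory (TriggerTime per
    file).  With no source, uniform spacing over ``cycle_ms`` is used.
    """
    if source is None:
        if cycle_ms is None:
            raise FormatError("need cycle_ms when no frame-time source is given")
        return np.arange(n_frames) * (float(cycle_ms) / n_frames)

    source = Path(source)
    if source.is_dir():
        times = _dicom_trigger_times(source)
    else:
        text = source.read_text().replace(",", "\n")
        times = np.array([float(tok) for tok in text.split() if tok.strip()])
    if len(times) != n_frames:
        raise FormatError(f"{len(times)} frame times for {n_frames} frames")
    if np.any(np.diff(times) <= 0):
        raise FormatError("frame times must be strictly increasing")
    return times.astype(np.float64)


def _dicom_trigger_times(directory: Path) -> np.ndarray:
    import pydicom

    times = []
    for f in sorted(directory.iterdir()):
        try:
            ds = pydicom.dcmread(str(f), stop_before_pixels=True)
        except Exception:
            continue
        t = getattr(ds, "TriggerTime", None)
        if t is not None:
            times.append(float(t))
    if not times:
        raise FormatError(f"no DICOM trigger times found under {directory}")
    return np.array(sorted(set(times)))


def normalize_intensity(values: np.ndarray) -> np.ndarray:
    """Per-volume min-max normalisation to [0, 1] (constant volumes -> 0)."""
    vmin, vmax = float(np.min(values)), float(np.max(values))
    if vmax - vmin < 1e-12:
        return np.zeros_like(values, dtype=np.float64)
    return (np.asarray(values, dtype=np.float64) - vmin) / (vmax - vmin)
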