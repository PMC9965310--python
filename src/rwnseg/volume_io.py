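"""Volume reading, ROI cropping, and isotropic resampling.

All geometry lives in LPS world coordinates (DICOM convention), in mm,
with 0-based voxel indices. A voxel's world position is::

    world = origin + orientation @ (index * spacing)

where ``origin`` is the center of voxel (0, 0, 0).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import _dicom, _nrrd
from .errors import FormatError, GeometryError, InputError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_ROI_EDGE_MM = 5.0
#: working resolution; inputs coarser than this are internally upsampled
WORKING_RESOLUTION_MM = 0.1


@dataclass
class VolumeImage:
    """A 3-D scalar grid with physical placement metadata."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise GeometryError("volume grid must be 3-D and non-empty")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if self.orientation.shape != (3, 3):
            raise GeometryError("orientation must be a 3x3 matrix")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-6):
            raise GeometryError("orientation must be orthonormal")
        if np.linalg.det(self.orientation) < 0:
            raise GeometryError("orientation must have determinant +1")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, indices) -> np.ndarray:
        """Map (continuous) voxel indices (..., 3) to world mm."""
        idx = np.asarray(indices, dtype=float)
        return self.origin + (idx * self.spacing) @ self.orientation.T

    def world_to_index(self, points) -> np.ndarray:
        """Map world points (..., 3) to continuous voxel indices."""
        pts = np.asarray(points, dtype=float)
        return ((pts - self.origin) @ self.orientation) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        grids = np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij")
        idx = np.stack(grids, axis=-1)
        return self.index_to_world(idx)

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Same grid geometry, different voxel values."""
        return replace(self, data=np.asarray(data))


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned world cube around the estimated niche position."""

    center: np.ndarray
    edge_length: float = DEFAULT_ROI_EDGE_MM

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not (self.edge_length > 0):
            raise ParameterError(f"ROI edge length must be > 0, got {self.edge_length}")


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "dicom_series"
    lower = path.lower()
    if lower.endswith(".nrrd") or lower.endswith(".nhdr"):
        return "nrrd"
    if lower.endswith(".nii") or lower.endswith(".nii.gz"):
        return "nifti"
    raise InputError(f"cannot infer volume format from path {path!r}")


_LPS_FLIP = np.diag([-1.0, -1.0, 1.0])


def read_volume(path: str, format: str | None = None) -> VolumeImage:
    """Read a volume from a DICOM series directory, NRRD, or NIfTI file.

    DICOM rescale slope/intercept are applied on read so intensities are
    HV-like. NIfTI affines (RAS) are converted to LPS.
    """
    if not os.path.exists(path):
        raise InputError(f"volume path does not exist: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nrrd":
        data, meta = _nrrd.read_nrrd(path)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D NRRD, got {data.ndim}-D")
        return VolumeImage(data, meta["spacing"], meta["origin"], meta["orientation"])
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(path)
        affine_lps = _LPS_FLIP_4 @ img.affine
        mat = affine_lps[:3, :3]
        spacing = np.linalg.norm(mat, axis=0)
        return VolumeImage(
            np.asarray(img.dataobj), spacing, affine_lps[:3, 3], mat / spacing
        )
    if fmt == "dicom_series":
        data, meta = _dicom.read_series(path)
        return VolumeImage(data, meta["spacing"], meta["origin"], meta["orientation"])
    raise InputError(f"unknown volume format {fmt!r}")


_LPS_FLIP_4 = np.diag([-1.0, -1.0, 1.0, 1.0])


def write_volume(vol: VolumeImage, path: str, format: str | None = None) -> None:
    """Write a volume; format inferred from the path when not given."""
    fmt = format or _infer_format(path)
    if fmt == "nrrd":
        _nrrd.write_nrrd(path, vol.data, vol.spacing, vol.origin, vol.orientation)
        return
    if fmt == "nifti":
        import nibabel as nib

        affine_lps = np.eye(4)
        affine_lps[:3, :3] = vol.orientation * vol.spacing[np.newaxis, :]
        affine_lps[:3, 3] = vol.origin
        img = nib.Nifti1Image(np.asarray(vol.data), _LPS_FLIP_4 @ affine_lps)
        nib.save(img, path)
        return
    if fmt == "dicom_series":
        _dicom.write_series(path, vol.data, vol.spacing, vol.origin, vol.orientation)
        return
    raise InputError(f"unknown volume format {fmt!r}")


def crop_roi(vol: VolumeImage, roi: RegionOfInterest) -> VolumeImage:
    """Crop the cubic working ROI out of a volume.

    Voxels whose centers lie in the closed world cube
    ``[center - e/2, center + e/2]`` are retained; world coordinates of
    retained voxels are unchanged. The cube is clamped to the volume; a
    ROI larger than the volume returns the full volume with a warning.
    For non-axis-aligned volumes the crop is the smallest index box
    containing the cube's preimage.
    """
    half = roi.edge_length / 2.0
    corners = roi.center + np.array(
        [[sx * half, sy * half, sz * half] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    idx = vol.world_to_index(corners)
    eps = 1e-9
    lo = np.ceil(idx.min(axis=0) - eps).astype(int)
    hi = np.floor(idx.max(axis=0) + eps).astype(int)

    shape = np.array(vol.shape)
    if np.any(hi < 0) or np.any(lo > shape - 1):
        raise GeometryError("ROI lies entirely outside the volume")
    clamped_lo = np.maximum(lo, 0)
    clamped_hi = np.minimum(hi, shape - 1)
    if np.any(lo < 0) or np.any(hi > shape - 1):
        log.warning(
            "ROI (edge %.3f mm at %s) exceeds the volume; crop clamped to the volume",
            roi.edge_length, np.round(roi.center, 3),
        )

    sl = tuple(slice(a, b + 1) for a, b in zip(clamped_lo, clamped_hi))
    return VolumeImage(
        vol.data[sl].copy(),
        vol.spacing,
        vol.index_to_world(clamped_lo),
        vol.orientation,
    )


def resample_isotropic(vol: VolumeImage, target: float) -> VolumeImage:
    """Resample to an isotropic grid when the input is coarser.

    If every input spacing is already <= ``target`` the input is returned
    unchanged; otherwise the grid is trilinearly interpolated to isotropic
    ``target`` spacing covering the same physical extent. Sampling clamps
    to the input grid so no value is extrapolated.
    """
    if not (isinstance(target, (int, float)) and math.isfinite(target)):
        raise ParameterError(f"resample target must be finite, got {target!r}")
    if target <= 0:
        raise ParameterError(f"resample target must be > 0, got {target}")
    if np.all(vol.spacing <= target + 1e-12):
        return vol

    extent = np.array(vol.shape) * vol.spacing
    n_out = np.maximum(1, np.round(extent / target)).astype(int)
    # axis coordinate of output voxel i (measured from the old voxel-0 center)
    coords = [
        (0.5 * (target - vol.spacing[a]) + np.arange(n_out[a]) * target) / vol.spacing[a]
        for a in range(3)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    resampled = ndimage.map_coordinates(
        vol.data.astype(np.float64), np.stack(grid), order=1, mode="nearest"
    )
    new_origin = vol.origin + vol.orientation @ (0.5 * (target - vol.spacing))
    return VolumeImage(resampled, np.full(3, float(target)), new_origin, vol.orientation)
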