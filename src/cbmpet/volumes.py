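"""Volumetric containers and NIfTI-1 I/O.

A :class:`VolumeImage` is the carrier for PET-like data: a 3-D scalar grid
plus a 4x4 voxel-to-world affine (RAS, mm).  A :class:`LabelVolume` carries
the tissue segmentation used throughout the pipeline with the fixed
enumeration ``0=background/CSF, 1=gray matter, 2=white matter,
3=cerebellum reference``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import FormatError, GeometryError

__all__ = [
    "BACKGROUND",
    "GRAY",
    "WHITE",
    "CEREBELLUM_REF",
    "LABEL_VALUES",
    "VolumeImage",
    "LabelVolume",
    "read_volume",
    "write_volume",
]

BACKGROUND = 0
GRAY = 1
WHITE = 2
CEREBELLUM_REF = 3
LABEL_VALUES = (BACKGROUND, GRAY, WHITE, CEREBELLUM_REF)


@dataclass
class VolumeImage:
    """3-D scalar grid with voxel geometry.

    Parameters
    ----------
    data
        3-D array of intensities (arbitrary units).
    affine
        4x4 voxel-to-world transform, world coordinates in mm (RAS).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume data contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise GeometryError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise GeometryError(f"non-positive voxel size {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """(dx, dy, dz) in mm: column norms of the linear part."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def like(self, data: np.ndarray) -> "VolumeImage":
        """New volume with the same geometry and different data."""
        return VolumeImage(np.asarray(data, dtype=np.float64), self.affine.copy())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class LabelVolume:
    """Integer tissue segmentation on a voxel grid (same geometry rules)."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("label volume contains non-integer values")
            arr = np.round(arr).astype(np.int32)
        self.labels = arr.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.labels.ndim != 3:
            raise GeometryError("expected a 3-D label volume")
        bad = np.setdiff1d(np.unique(self.labels), LABEL_VALUES)
        if bad.size:
            raise FormatError(
                f"label values {bad.tolist()} outside the enumeration {LABEL_VALUES}"
            )
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise GeometryError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def mask(self, value: int) -> np.ndarray:
        return self.labels == value

    def as_volume(self) -> VolumeImage:
        return VolumeImage(self.labels.astype(np.float64), self.affine.copy())


def read_volume(path, labels: bool = False):
    """Read a NIfTI-1 volume.

    With ``labels=True`` the data are validated against the tissue
    enumeration and returned as a :class:`LabelVolume`.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if labels:
        return LabelVolume(data, affine)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path} contains non-finite voxels")
    return VolumeImage(data.astype(np.float64), affine)


def write_volume(volume, path) -> None:
    """Write a :class:`VolumeImage` or :class:`LabelVolume` as NIfTI-1."""
    if isinstance(volume, LabelVolume):
        img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine)
    else:
        img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))
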