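"""Volumetric containers and I/O.

The package works on 3D scalar grids in a Hounsfield-unit-like scale together
with binary label maps that share the grid.  The voxel model is fixed: voxel
centers sit at ``origin + direction @ (index * spacing)``, indices are 0-based
and the in-memory axis order is ``(x, y, z)`` of the grid.  World coordinates
are millimetres.  The canonical internal orientation is LPS
(left-posterior-superior, the DICOM patient frame); files are reoriented at
read time and no operation ever resamples implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LabelMap",
    "GridMismatchError",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "reorient_to_lps",
]

_META_ATOL = 1e-5


class GridMismatchError(ValueError):
    """Two grids that must be aligned (shape, spacing, origin, direction) differ."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical metadata.

    Parameters
    ----------
    data
        Scalar array indexed ``(x, y, z)``.
    spacing
        Voxel spacing in mm, one entry per grid axis; strictly positive.
    origin
        World coordinates (mm) of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 direction-cosine matrix mapping grid axes to world axes.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    direction: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be a positive 3-vector (mm)")
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        )
        self.direction = (
            np.eye(3)
            if self.direction is None
            else np.asarray(self.direction, dtype=float).reshape(3, 3)
        )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for fractional indices ``idx`` (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - self.origin) @ np.linalg.inv(self.direction).T) / self.spacing

    def same_grid(self, other: "ImageVolume | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_META_ATOL)
            and np.allclose(self.origin, other.origin, atol=_META_ATOL)
            and np.allclose(self.direction, other.direction, atol=_META_ATOL)
        )

    def check_same_grid(self, other: "ImageVolume | LabelMap", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} are not on the same grid "
                f"(shape {self.shape} vs {other.shape}); resample explicitly"
            )


@dataclass
class LabelMap(ImageVolume):
    """Binary mask on the same grid model as :class:`ImageVolume` (values in {0, 1})."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"label map must be binary, found values {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def volume_mm3(self) -> float:
        """Total labelled volume in mm^3."""
        return float(self.data.sum()) * self.voxel_volume_mm3


# ---------------------------------------------------------------------------
# SimpleITK bridge.  sitk stores arrays (z, y, x); we keep (x, y, z).

def _from_sitk(img: sitk.Image) -> ImageVolume:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(
        data=data,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    img.SetDirection(tuple(vol.direction.ravel()))
    return img


def read_volume(path: str | Path, *, to_lps: bool = True) -> ImageVolume:
    """Read a NIfTI-1 (.nii/.nii.gz) or NRRD scalar volume.

    By default the volume is reoriented to the canonical LPS frame; world
    coordinates of every voxel are unchanged by the reorientation.
    """
    img = sitk.ReadImage(str(path))
    vol = _from_sitk(img)
    return reorient_to_lps(vol) if to_lps else vol


def read_labels(path: str | Path, *, to_lps: bool = True) -> LabelMap:
    vol = read_volume(path, to_lps=to_lps)
    return LabelMap(np.rint(vol.data), vol.spacing, vol.origin, vol.direction)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write to NIfTI-1 or NRRD, chosen from the file extension."""
    sitk.WriteImage(_to_sitk(vol), str(path))


def write_labels(labels: LabelMap, path: str | Path) -> None:
    img = _to_sitk(ImageVolume(labels.data.astype(np.uint8), labels.spacing,
                               labels.origin, labels.direction))
    sitk.WriteImage(img, str(path))


def reorient_to_lps(vol: ImageVolume) -> ImageVolume:
    """Permute/flip grid axes so that they follow the LPS convention.

    Idempotent; the physical (world) position of every voxel is preserved,
    only the index order changes.
    """
    det = np.linalg.det(vol.direction)
    if abs(det) < 1e-9:
        raise ValueError("singular direction matrix")
    img = _to_sitk(vol)
    out = sitk.DICOMOrient(img, "LPS")
    res = _from_sitk(out)
    if isinstance(vol, LabelMap):
        return LabelMap(np.rint(res.data), res.spacing, res.origin, res.direction)
    return res
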