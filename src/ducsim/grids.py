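"""In-memory containers for CT volumes and binary region-of-interest masks.

Arrays are indexed ``[x, y, z]`` with ``z`` the axial (slice) axis, so an
axial slice is the 2D array ``volume.intensities[:, :, z]``.  All physical
quantities are millimetres, derived from per-axis voxel ``spacing``.
Indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import DisconnectedSliceError, GeometryError

__all__ = ["CTVolume", "ROIMask", "KNOWN_ROIS"]

KNOWN_ROIS = ("prostate", "bladder", "rectum", "other")

# 8-connectivity structuring element for in-plane component labelling
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def _check_spacing(spacing):
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GeometryError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3D intensity grid on the Hounsfield-unit scale.

    Attributes
    ----------
    intensities
        ``(nx, ny, nz)`` float array of HU values; must be finite.
    spacing
        ``(dx, dy, dz)`` voxel size in mm, all strictly positive.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise GeometryError("intensities must be a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise GeometryError("intensities must be finite")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def axial_slice(self, z: int) -> np.ndarray:
        """Return the (x, y) intensity plane at slice index ``z``."""
        return self.intensities[:, :, z]


@dataclass
class ROIMask:
    """A binary organ mask aligned to a :class:`CTVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    roi_name: str = "other"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise GeometryError("mask must be a 3D array")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def nonempty_slices(self) -> np.ndarray:
        """Indices of axial slices containing any foreground, ascending."""
        return np.flatnonzero(self.voxels.any(axis=(0, 1)))

    def check_alignment(self, other) -> None:
        """Raise if ``other`` (mask or volume) lives on a different grid."""
        if self.shape != other.shape or self.spacing != other.spacing:
            raise GeometryError(
                f"grid mismatch: {self.shape}@{self.spacing} vs {other.shape}@{other.spacing}"
            )

    def validate(self) -> None:
        """Enforce the mask contract assumed by the perturbation model.

        Every nonempty axial slice must hold exactly one 8-connected
        foreground component, and the nonempty slices must form one
        contiguous z-range.
        """
        zs = self.nonempty_slices()
        if zs.size == 0:
            return
        if not np.array_equal(zs, np.arange(zs[0], zs[-1] + 1)):
            raise GeometryError("nonempty slices do not form a contiguous z-range")
        bad = []
        for z in zs:
            _, n = ndi.label(self.voxels[:, :, z], structure=_STRUCT_8)
            if n != 1:
                bad.append(int(z))
        if bad:
            raise DisconnectedSliceError(bad)

    def copy(self) -> "ROIMask":
        return ROIMask(self.voxels.copy(), self.spacing, self.roi_name)
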