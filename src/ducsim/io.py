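"""Reading and writing volumes and masks (NIfTI, NRRD, DICOM RT-STRUCT).

Arrays are kept in the package's ``[x, y, z]`` index order.  NIfTI goes
through nibabel (the on-disk (i, j, k) data order maps directly); NRRD goes
through SimpleITK (whose array order (z, y, x) is transposed on the way in
and out).  Masks are written as unsigned 8-bit volumes with values {0, 1}.

The RT-STRUCT support is read-only: contour sequences are rasterized onto a
given CT grid by nearest-slice assignment and in-plane polygon fill.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk

from .contours import fill_loop
from .errors import DucsimError
from .grids import CTVolume, ROIMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "masks_from_rtstruct",
]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _read_array(path) -> tuple[np.ndarray, tuple]:
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, spacing
    if path.suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return data, tuple(float(s) for s in img.GetSpacing())
    raise DucsimError(f"unsupported volume format: {path.name}")


def _write_array(data: np.ndarray, spacing, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if path.suffix == ".nrrd":
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
        return
    raise DucsimError(f"unsupported volume format: {path.name}")


def read_volume(path) -> CTVolume:
    """Load a CT intensity volume from .nii/.nii.gz/.nrrd."""
    data, spacing = _read_array(path)
    return CTVolume(data.astype(float), spacing)


def write_volume(vol: CTVolume, path) -> None:
    _write_array(vol.intensities.astype(np.float32), vol.spacing, path)


def read_mask(path, roi_name: str = "other") -> ROIMask:
    """Load a binary mask (any nonzero voxel counts as foreground)."""
    data, spacing = _read_array(path)
    return ROIMask(data > 0, spacing, roi_name)


def write_mask(mask: ROIMask, path) -> None:
    _write_array(mask.voxels.astype(np.uint8), mask.spacing, path)


def masks_from_rtstruct(
    rtstruct,
    ct: CTVolume,
    origin=(0.0, 0.0, 0.0),
    roi_names=None,
) -> dict[str, ROIMask]:
    """Rasterize RT-STRUCT contour sequences onto a CT grid.

    Assumes an axis-aligned grid: patient coordinates map to voxel indices
    via ``(p - origin) / spacing``.  Each planar contour is assigned to the
    nearest axial slice and filled as a polygon; several contours on one
    slice are OR-ed together.

    Parameters
    ----------
    rtstruct
        A ``pydicom`` dataset or a path to one.
    roi_names
        Optional subset of ROI names to rasterize (default: all).
    """
    ds = rtstruct if isinstance(rtstruct, pydicom.Dataset) else pydicom.dcmread(str(rtstruct))
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(ct.spacing, dtype=float)
    nx, ny, nz = ct.shape

    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in ds.StructureSetROISequence
    }
    out: dict[str, ROIMask] = {}
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), f"roi{roi.ReferencedROINumber}")
        if roi_names is not None and name not in roi_names:
            continue
        voxels = np.zeros(ct.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            vox = (pts - origin) / spacing
            z = int(round(float(np.mean(vox[:, 2]))))
            if not 0 <= z < nz:
                continue
            voxels[:, :, z] |= fill_loop(vox[:, :2], (nx, ny))
        out[name] = ROIMask(voxels, ct.spacing, roi_name=name if name in
                            ("prostate", "bladder", "rectum") else "other")
    return out
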