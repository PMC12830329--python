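"""NIfTI interchange: the array+metadata format accepted everywhere DICOM is.

The on-disk NIfTI affine stores (x, y, z) world coordinates; the in-memory
containers use (slice, row, column) = (z, y, x).  Only axis-aligned,
positive-spacing affines are supported — a deliberate restriction that
matches the axial planning-CT geometry handled by the DICOM readers.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import DoseGrid, GeometryError, ImageVolume, StructureMask


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_zyx[2], spacing_zyx[1], spacing_zyx[0]
    aff[:3, 3] = [origin_zyx[2], origin_zyx[1], origin_zyx[0]]
    return aff


def _geometry_from(img) -> tuple[tuple, tuple]:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise GeometryError("only axis-aligned NIfTI affines are supported")
    d = np.diag(aff[:3, :3])
    if np.any(d <= 0):
        raise GeometryError("NIfTI affine must have positive spacing on all axes")
    spacing = (float(d[2]), float(d[1]), float(d[0]))
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return spacing, origin


def write_volume(volume: ImageVolume | DoseGrid, path: str | Path) -> None:
    data = np.asarray(volume.voxels).transpose(2, 1, 0)  # (x, y, z) on disk
    img = nib.Nifti1Image(data.astype(np.float32), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing, origin = _geometry_from(img)
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    return ImageVolume(voxels=data, spacing=spacing, origin=origin)


def read_dose(path: str | Path, fractions: int | None = None) -> DoseGrid:
    img = nib.load(str(path))
    spacing, origin = _geometry_from(img)
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    return DoseGrid(voxels=data, spacing=spacing, origin=origin, fractions=fractions)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    data = mask.voxels.astype(np.uint8).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, _affine(mask.spacing, mask.origin)), str(path))


def read_mask(path: str | Path, name: str | None = None) -> StructureMask:
    img = nib.load(str(path))
    spacing, origin = _geometry_from(img)
    data = np.asarray(img.dataobj).transpose(2, 1, 0) > 0
    return StructureMask(
        name=name or Path(path).stem.replace(".nii", ""),
        voxels=data,
        spacing=spacing,
        origin=origin,
    )


def write_label_map(
    labels: dict[int, StructureMask], path: str | Path
) -> None:
    """Write disjoint masks as one integer label map (later keys win)."""
    first = next(iter(labels.values()))
    out = np.zeros(first.shape, dtype=np.uint8)
    for value, mask in labels.items():
        first.check_congruent(mask)
        out[mask.voxels] = value
    nib.save(
        nib.Nifti1Image(out.transpose(2, 1, 0), _affine(first.spacing, first.origin)),
        str(path),
    )
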