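"""DICOM readers/writers for CT series, RT Structure Sets and RT Dose.

Only the geometry actually needed by the pipeline is handled: axial series
with uniform slice spacing and axis-aligned orientation (the standard
supine planning-CT layout).  Anything else fails with a descriptive error
rather than silently producing a mis-registered grid.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volumes import DoseGrid, GeometryError, ImageVolume, StructureMask, contours_to_mask

_AXIAL_ORIENTATION = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
_SLICE_TOL_MM = 0.01


def read_ct_series(path: str | Path) -> ImageVolume:
    """Read a single axial CT series from a directory of DICOM files.

    Rescale slope/intercept are applied so voxel values are HU; slices are
    ordered by patient z position.  Mixed series, missing geometry tags and
    non-uniform slice spacing raise :class:`GeometryError`.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT":
            datasets.append(ds)
    if not datasets:
        raise GeometryError(f"no CT slices found under {path}")

    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) > 1:
        raise GeometryError(f"directory contains {len(series_uids)} CT series; expected one")
    for ds in datasets:
        for tag in ("ImagePositionPatient", "PixelSpacing", "ImageOrientationPatient"):
            if tag not in ds:
                raise GeometryError(f"CT slice {ds.filename} is missing {tag}")
        if not np.allclose([float(v) for v in ds.ImageOrientationPatient], _AXIAL_ORIENTATION):
            raise GeometryError("only axis-aligned axial CT series are supported")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise GeometryError("duplicate or non-monotonic slice positions")
        if np.ptp(dz) > _SLICE_TOL_MM:
            gaps = np.where(np.abs(dz - np.median(dz)) > _SLICE_TOL_MM)[0]
            gap_z = ", ".join(f"{zs[g]:.2f}->{zs[g + 1]:.2f} mm" for g in gaps)
            raise GeometryError(
                f"non-uniform slice spacing (possible missing slices) between {gap_z}"
            )
        spacing_z = float(np.median(dz))
    else:
        spacing_z = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    first = datasets[0]
    ps = [float(v) for v in first.PixelSpacing]  # (row, col)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    voxels = np.stack(slices, axis=0)
    origin = (
        zs[0],
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[0]),
    )
    return ImageVolume(voxels=voxels, spacing=(spacing_z, ps[0], ps[1]), origin=origin)


def write_ct_series(volume: ImageVolume, path: str | Path, patient_id: str = "PHANTOM") -> None:
    """Write an :class:`ImageVolume` as an axial CT series (int16 HU)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    data = np.round(volume.voxels).astype(np.int16)
    for k in range(volume.shape[0]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.PatientID = patient_id
        ds.PatientName = patient_id
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = list(_AXIAL_ORIENTATION)
        z = volume.origin[0] + k * volume.spacing[0]
        ds.ImagePositionPatient = [volume.origin[2], volume.origin[1], z]
        ds.PixelSpacing = [volume.spacing[1], volume.spacing[2]]
        ds.SliceThickness = volume.spacing[0]
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = data[k].tobytes()
        ds.save_as(path / f"ct_{k:04d}.dcm", enforce_file_format=True)


def read_structures(path: str | Path, reference: ImageVolume) -> list[StructureMask]:
    """Read an RT Structure Set and rasterize every ROI onto the reference
    CT grid (voxel-centre-in-polygon, per axial slice)."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise GeometryError(f"{path} is not an RT Structure Set")
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    masks = []
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi_contour.ReferencedROINumber), "unnamed")
        contours = []
        for c in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(pts)
        if not contours:
            warnings.warn(f"structure '{name}' has no contours; empty mask", stacklevel=2)
            masks.append(
                StructureMask.from_reference(name, np.zeros(reference.shape, bool), reference)
            )
            continue
        masks.append(contours_to_mask(contours, reference, name=name))
    return masks


def write_structures(
    masks: list[StructureMask], path: str | Path, patient_id: str = "PHANTOM"
) -> None:
    """Write masks as an RT Structure Set (contours traced per slice)."""
    from .volumes import mask_to_contours

    path = Path(path)
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = pydicom.uid.RTStructureSetStorage
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.StructureSetLabel = "breastcomp"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, mask in enumerate(masks, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = mask.name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for contour in mask_to_contours(mask):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(contour)
            c.ContourData = [float(v) for v in contour.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


def read_rt_dose(path: str | Path, fractions: int | None = None) -> DoseGrid:
    """Read an RT Dose grid; DoseGridScaling is applied to give Gy."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise GeometryError(f"{path} is not an RT Dose file")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    voxels = ds.pixel_array.astype(np.float64) * scaling
    ps = [float(v) for v in ds.PixelSpacing]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if np.ptp(dz) > _SLICE_TOL_MM:
            raise GeometryError("non-uniform dose grid frame offsets")
        spacing_z = float(dz[0])
    else:
        spacing_z = 1.0
    ipp = [float(v) for v in ds.ImagePositionPatient]
    origin = (ipp[2] + offsets[0], ipp[1], ipp[0])
    return DoseGrid(
        voxels=voxels, spacing=(spacing_z, ps[0], ps[1]), origin=origin, fractions=fractions
    )


def write_rt_dose(dose: DoseGrid, path: str | Path, patient_id: str = "PHANTOM") -> None:
    """Write a dose grid as an RT Dose file (uint32 with DoseGridScaling)."""
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = pydicom.uid.RTDoseStorage
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    scaling = max(float(dose.voxels.max()), 1e-6) / (2**31)
    data = np.round(dose.voxels / scaling).astype(np.uint32)
    ds.DoseGridScaling = scaling
    ds.ImageOrientationPatient = list(_AXIAL_ORIENTATION)
    ds.ImagePositionPatient = [dose.origin[2], dose.origin[1], dose.origin[0]]
    ds.PixelSpacing = [dose.spacing[1], dose.spacing[2]]
    ds.GridFrameOffsetVector = [k * dose.spacing[0] for k in range(dose.shape[0])]
    ds.Rows, ds.Columns = dose.shape[1], dose.shape[2]
    ds.NumberOfFrames = dose.shape[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = data.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
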