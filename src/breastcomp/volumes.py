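"""Voxel-grid containers and geometric operations.

All grids use a single convention: world coordinates are patient-based
millimetres (LPS), voxel indices are 0-based with axis order
``(slice, row, column)`` = (z, y, x), and a mask stores voxel-centre
membership.  ``spacing`` and ``origin`` are given in the same (z, y, x)
order, so the world position of voxel ``(k, j, i)`` is
``origin + (k, j, i) * spacing``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when grids are spatially inconsistent or degenerate."""


@dataclass(frozen=True)
class ImageVolume:
    """A scalar CT volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        HU values, axis order (slice, row, column).
    spacing : tuple of float
        Voxel spacing in mm, (z, y, x); all entries > 0.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float32)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise GeometryError(f"volume must be 3-D with shape >= (1,1,1), got {vox.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(vox)):
            raise GeometryError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def world_coordinates(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates along one axis (0=z, 1=y, 2=x)."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass(frozen=True)
class StructureMask:
    """A boolean mask congruent with a reference :class:`ImageVolume`."""

    name: str
    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=bool)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if vox.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got shape {vox.shape}")

    @classmethod
    def from_reference(cls, name: str, voxels: np.ndarray, ref: ImageVolume) -> "StructureMask":
        voxels = np.asarray(voxels, dtype=bool)
        if voxels.shape != ref.shape:
            raise GeometryError(
                f"mask shape {voxels.shape} does not match reference {ref.shape}"
            )
        return cls(name=name, voxels=voxels, spacing=ref.spacing, origin=ref.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def volume_cm3(self) -> float:
        return self.count() * float(np.prod(self.spacing)) / 1000.0

    def check_congruent(self, other) -> None:
        if self.shape != other.shape:
            raise GeometryError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing) or not np.allclose(
            self.origin, other.origin
        ):
            raise GeometryError("spacing/origin mismatch between grids")


@dataclass(frozen=True)
class DoseGrid:
    """An absorbed-dose grid (Gy) with its own geometry and fraction count.

    ``fractions`` is the number of delivered fractions; it is required for
    the linear-quadratic EQD2 conversion and may be ``None`` for grids that
    are only used for physical-dose metrics.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fractions: int | None = None
    outside_extent: np.ndarray | None = None  # voxels filled with 0 at resampling

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float64)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if vox.ndim != 3:
            raise GeometryError(f"dose grid must be 3-D, got shape {vox.shape}")
        if np.any(vox < -1e-9):
            raise GeometryError("dose must be non-negative")
        if self.fractions is not None and int(self.fractions) < 1:
            raise GeometryError(f"fractions must be >= 1, got {self.fractions}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)


# ---------------------------------------------------------------------------
# contour rasterization


def contours_to_mask(
    contours: list[np.ndarray],
    reference: ImageVolume,
    name: str = "structure",
) -> StructureMask:
    """Rasterize closed planar contours onto the reference grid.

    Each contour is an (n, 3) array of world-mm points ``(x, y, z)`` on a
    single axial plane (constant z).  Membership is voxel-centre-in-polygon,
    evaluated per slice with matplotlib's point-in-path test; contours on
    the same slice are XOR-combined so holes are supported.  Contours lying
    outside the grid are clipped (off-grid slices dropped with a warning).
    """
    from matplotlib.path import Path

    mask = np.zeros(reference.shape, dtype=bool)
    zs = reference.world_coordinates(0)
    ys = reference.world_coordinates(1)
    xs = reference.world_coordinates(2)
    xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
    centers = np.column_stack([xx.ravel(), yy.ravel()])

    for contour in contours:
        contour = np.asarray(contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 3 or contour.shape[0] < 3:
            raise GeometryError("each contour must be an (n>=3, 3) array of x,y,z points")
        z = float(np.mean(contour[:, 2]))
        k = int(np.argmin(np.abs(zs - z)))
        if abs(zs[k] - z) > reference.spacing[0] / 2 + 1e-6:
            warnings.warn(
                f"contour at z={z:.2f} mm lies outside the grid; clipped", stacklevel=2
            )
            continue
        path = Path(contour[:, :2])
        inside = path.contains_points(centers).reshape(len(ys), len(xs))
        mask[k] ^= inside

    if not mask.any():
        warnings.warn(f"structure '{name}' rasterized to an empty mask", stacklevel=2)
    return StructureMask.from_reference(name, mask, reference)


def mask_to_contours(mask: StructureMask) -> list[np.ndarray]:
    """Polygonize a mask slice-by-slice into closed planar world contours.

    Sub-voxel boundaries are traced at the 0.5 iso-level of the padded
    binary slice, the approximate inverse of :func:`contours_to_mask`.
    """
    from skimage import measure

    contours: list[np.ndarray] = []
    zs = mask.origin[0] + mask.spacing[0] * np.arange(mask.shape[0])
    for k in range(mask.shape[0]):
        sl = mask.voxels[k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        for poly in measure.find_contours(padded, 0.5):
            # poly is (n, 2) in (row, col) of the padded slice
            rows = poly[:, 0] - 1.0
            cols = poly[:, 1] - 1.0
            x = mask.origin[2] + cols * mask.spacing[2]
            y = mask.origin[1] + rows * mask.spacing[1]
            z = np.full(len(poly), zs[k])
            contours.append(np.column_stack([x, y, z]))
    return contours


# ---------------------------------------------------------------------------
# dose resampling


def resample_dose_to_ct(dose: DoseGrid, ct: ImageVolume) -> DoseGrid:
    """Trilinearly interpolate a dose grid onto the CT geometry.

    CT voxels whose centres fall outside the dose extent receive 0 Gy and
    are flagged in ``outside_extent``.  Raises if the extents are disjoint.
    """
    # CT voxel-centre positions expressed in dose index space
    coords = []
    any_overlap = []
    for ax in range(3):
        w = ct.world_coordinates(ax)
        idx = (w - dose.origin[ax]) / dose.spacing[ax]
        coords.append(idx)
        any_overlap.append(np.any((idx >= -0.5) & (idx <= dose.shape[ax] - 0.5)))
    if not all(any_overlap):
        raise GeometryError("dose grid and CT volume have disjoint spatial extents")

    kk, jj, ii = np.meshgrid(*coords, indexing="ij")
    sampled = ndimage.map_coordinates(
        dose.voxels, [kk, jj, ii], order=1, mode="constant", cval=0.0
    )
    outside = (
        (kk < 0) | (kk > dose.shape[0] - 1)
        | (jj < 0) | (jj > dose.shape[1] - 1)
        | (ii < 0) | (ii > dose.shape[2] - 1)
    )
    sampled[outside] = 0.0
    return DoseGrid(
        voxels=sampled,
        spacing=ct.spacing,
        origin=ct.origin,
        fractions=dose.fractions,
        outside_extent=outside,
    )


# ---------------------------------------------------------------------------
# skin cropping


def skin_distance_mm(body: StructureMask) -> np.ndarray:
    """Distance (mm) from each in-body voxel centre to the nearest
    outside-body voxel centre, computed at native anisotropic spacing."""
    return ndimage.distance_transform_edt(body.voxels, sampling=body.spacing)


def crop_from_skin(
    breast: StructureMask, body: StructureMask, margin_mm: float = 5.0
) -> StructureMask:
    """Remove the breast rind within ``margin_mm`` of the skin surface.

    Breast voxels whose Euclidean distance to the nearest outside-body voxel
    centre is <= ``margin_mm`` are removed; superficial dose and skin-dose
    artefacts are thereby excluded from all downstream composition and dose
    metrics.  Breast voxels outside the body are dropped with a warning.
    ``margin_mm = 0`` returns the (body-restricted) input unchanged.
    """
    breast.check_congruent(body)
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    inside = breast.voxels & body.voxels
    n_outside = int(breast.voxels.sum() - inside.sum())
    if n_outside:
        warnings.warn(
            f"{n_outside} breast voxels outside the body mask were dropped",
            stacklevel=2,
        )
    if margin_mm == 0:
        cropped = inside
    else:
        dist = skin_distance_mm(body)
        cropped = inside & (dist > margin_mm)
    if not cropped.any():
        raise GeometryError(
            f"cropping {margin_mm} mm from skin removed the entire '{breast.name}' mask"
        )
    return replace(breast, voxels=cropped)
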