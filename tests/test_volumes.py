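"""Geometry: skin cropping, contour rasterization, dose resampling."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from breastcomp import (
    DoseGrid,
    GeometryError,
    ImageVolume,
    StructureMask,
    contours_to_mask,
    crop_from_skin,
    mask_to_contours,
    resample_dose_to_ct,
)


def brute_force_skin_distance(body: StructureMask) -> np.ndarray:
    """Independent oracle: exhaustive nearest-background-centre search."""
    spacing = np.asarray(body.spacing)
    inside = np.argwhere(body.voxels) * spacing
    outside = np.argwhere(~body.voxels) * spacing
    tree = cKDTree(outside)
    d, _ = tree.query(inside)
    out = np.zeros(body.shape)
    out[body.voxels] = d
    return out


class TestCropFromSkin:
    def test_slab_removes_exact_margin_layers(self, slab_geometry):
        ct, body, breast = slab_geometry
        cropped = crop_from_skin(breast, body, margin_mm=5)
        # the 5 voxel layers nearest the flat skin surface go (rows 8..12)
        expected = breast.voxels.copy()
        expected[:, 8:13, :] = False
        assert np.array_equal(cropped.voxels, expected)

    def test_zero_margin_is_identity(self, slab_geometry):
        _, body, breast = slab_geometry
        assert np.array_equal(crop_from_skin(breast, body, 0).voxels, breast.voxels)

    def test_monotone_in_margin(self, fatty_patient):
        p = fatty_patient
        bigger = crop_from_skin(p.breast, p.body, 8).voxels
        smaller = crop_from_skin(p.breast, p.body, 4).voxels
        assert not np.any(bigger & ~smaller)  # crop(8) subset of crop(4)

    def test_hemisphere_matches_exhaustive_distance_oracle(self, fatty_patient):
        p = fatty_patient
        margin = 5.0
        cropped = crop_from_skin(p.breast, p.body, margin)
        dist = brute_force_skin_distance(p.body)
        expected = p.breast.voxels & (dist > margin)
        assert np.array_equal(cropped.voxels, expected)

    def test_voxels_outside_body_dropped_with_warning(self, slab_geometry):
        ct, body, breast = slab_geometry
        leaky = breast.voxels.copy()
        leaky[:, 0, :] = True  # air rows
        leaky_mask = StructureMask.from_reference("breast", leaky, ct)
        with pytest.warns(UserWarning, match="outside the body"):
            cropped = crop_from_skin(leaky_mask, body, 0)
        assert not np.any(cropped.voxels & ~body.voxels)

    def test_margin_eliminating_mask_raises(self, slab_geometry):
        _, body, breast = slab_geometry
        with pytest.raises(GeometryError, match="entire"):
            crop_from_skin(breast, body, margin_mm=100)


class TestRasterization:
    def test_square_contour_analytic_area(self):
        ct = ImageVolume(np.zeros((3, 20, 20)), spacing=(1.0, 1.0, 1.0))
        # edges between voxel centres, so exactly 10x10 centres lie inside
        square = np.array(
            [[1.5, 1.5, 1.0], [11.5, 1.5, 1.0], [11.5, 11.5, 1.0], [1.5, 11.5, 1.0]]
        )
        mask = contours_to_mask([square], ct)
        assert mask.voxels[1].sum() == 100  # 10 x 10 mm on a 1 mm grid
        assert mask.voxels[0].sum() == 0 and mask.voxels[2].sum() == 0

    def test_polygonize_rasterize_round_trip(self, fatty_patient):
        breast = fatty_patient.breast
        contours = mask_to_contours(breast)
        back = contours_to_mask(contours, fatty_patient.ct, name="roundtrip")
        inter = np.sum(back.voxels & breast.voxels)
        dice = 2 * inter / (back.count() + breast.count())
        assert dice >= 0.99

    def test_off_grid_contour_gives_empty_mask_and_warning(self):
        ct = ImageVolume(np.zeros((3, 10, 10)), spacing=(1.0, 1.0, 1.0))
        far = np.array([[0.0, 0.0, 500.0], [5.0, 0.0, 500.0], [5.0, 5.0, 500.0]])
        with pytest.warns(UserWarning):
            mask = contours_to_mask([far], ct)
        assert mask.is_empty()


class TestResampleDose:
    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(0)
        ct = ImageVolume(rng.normal(0, 100, (8, 9, 10)), spacing=(2.0, 1.5, 1.0))
        dose = DoseGrid(rng.uniform(0, 50, (8, 9, 10)), spacing=ct.spacing,
                        origin=ct.origin, fractions=15)
        out = resample_dose_to_ct(dose, ct)
        np.testing.assert_allclose(out.voxels, dose.voxels, atol=1e-12)
        assert out.fractions == 15

    def test_constant_field_preserved(self):
        ct = ImageVolume(np.zeros((10, 10, 10)), spacing=(1.0, 1.0, 1.0))
        dose = DoseGrid(np.full((4, 4, 4), 40.0), spacing=(3.0, 3.0, 3.0),
                        origin=(0, 0, 0))
        out = resample_dose_to_ct(dose, ct)
        inside = ~out.outside_extent
        assert inside.any()
        np.testing.assert_allclose(out.voxels[inside], 40.0)
        np.testing.assert_allclose(out.voxels[~inside], 0.0)

    def test_linear_gradient_exact(self):
        # trilinear interpolation reproduces an affine plane to fp precision
        nz, ny, nx = 6, 7, 8
        z, y, x = np.meshgrid(
            2.0 * np.arange(nz), 2.0 * np.arange(ny), 2.0 * np.arange(nx), indexing="ij"
        )
        plane = 10.0 + 0.3 * x + 0.2 * y + 0.1 * z
        dose = DoseGrid(plane, spacing=(2.0, 2.0, 2.0), origin=(0, 0, 0))
        ct = ImageVolume(np.zeros((9, 11, 13)), spacing=(1.0, 1.0, 1.0),
                         origin=(0.5, 0.5, 0.5))
        out = resample_dose_to_ct(dose, ct)
        zc, yc, xc = np.meshgrid(
            ct.world_coordinates(0), ct.world_coordinates(1), ct.world_coordinates(2),
            indexing="ij",
        )
        expected = 10.0 + 0.3 * xc + 0.2 * yc + 0.1 * zc
        inside = ~out.outside_extent
        assert np.max(np.abs(out.voxels[inside] - expected[inside])) < 1e-6

    def test_disjoint_extents_raise(self):
        ct = ImageVolume(np.zeros((5, 5, 5)), spacing=(1.0, 1.0, 1.0))
        dose = DoseGrid(np.ones((5, 5, 5)), spacing=(1.0, 1.0, 1.0),
                        origin=(1000.0, 1000.0, 1000.0))
        with pytest.raises(GeometryError, match="disjoint"):
            resample_dose_to_ct(dose, ct)


class TestInvariants:
    def test_masks_congruent_with_reference(self, fatty_patient):
        p = fatty_patient
        for mask in (p.body, p.breast, p.fat_truth, p.fibro_truth):
            assert mask.geometry() == (p.ct.shape, p.ct.spacing, p.ct.origin)

    def test_volume_validation(self):
        with pytest.raises(GeometryError):
            ImageVolume(np.zeros((5, 5)), spacing=(1, 1, 1))
        with pytest.raises(GeometryError):
            ImageVolume(np.zeros((5, 5, 5)), spacing=(1, 0, 1))
        with pytest.raises(GeometryError):
            ImageVolume(np.full((2, 2, 2), np.nan), spacing=(1, 1, 1))
        with pytest.raises(GeometryError):
            DoseGrid(np.full((2, 2, 2), -1.0), spacing=(1, 1, 1))
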