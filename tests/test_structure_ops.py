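"""Contour rasterization, mask warping, DICE and structure sampling."""

import numpy as np
import pytest

from dvfcompare import (
    DisplacementField,
    GridGeometry,
    PlanarContour,
    ScalarVolume,
    StructureMask,
    dice,
    jacobian_map,
    make_affine_field,
    make_sphere_mask,
    rasterize_contours,
    sample_structure,
    warp_mask,
)


def brute_force_point_in_polygon(px, py, verts):
    """Independent even-odd oracle: count ray crossings one point at a time."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 <= py) != (y2 <= py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


class TestRasterize:
    square = ((0.5, 0.5), (10.5, 0.5), (10.5, 10.5), (0.5, 10.5))

    def test_square_voxel_count(self):
        # centers 1..10 in both axes lie strictly inside: 100 voxels
        geom = GridGeometry((16, 16, 4), (1.0, 1.0, 1.0))
        mask = rasterize_contours([PlanarContour(1, self.square)], geom, "sq")
        assert mask.voxel_count == 100
        assert mask.occupancy[:, :, [0, 2, 3]].sum() == 0  # other slices empty

    def test_orientation_free(self):
        geom = GridGeometry((16, 16, 4), (1.0, 1.0, 1.0))
        cw = rasterize_contours([PlanarContour(1, self.square)], geom)
        ccw = rasterize_contours([PlanarContour(1, self.square[::-1])], geom)
        np.testing.assert_array_equal(cw.occupancy, ccw.occupancy)

    def test_matches_brute_force_oracle_on_random_polygon(self, rng):
        geom = GridGeometry((20, 20, 3), (1.0, 1.0, 1.0))
        # star-shaped random polygon around (9.5, 9.5)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 9))
        radii = rng.uniform(3, 9, 9)
        verts = tuple(
            (9.5 + r * np.cos(t), 9.5 + r * np.sin(t)) for r, t in zip(radii, angles)
        )
        mask = rasterize_contours([PlanarContour(1, verts)], geom)
        for i in range(20):
            for j in range(20):
                assert mask.occupancy[i, j, 1] == brute_force_point_in_polygon(
                    float(i), float(j), verts
                )

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            PlanarContour(0, ((0, 0), (1, 1), (0, 0)))

    def test_empty_contour_list_rejected(self, small_grid):
        with pytest.raises(ValueError, match="empty"):
            rasterize_contours([], small_grid)


class TestWarpMask:
    def test_zero_field_is_identity(self, small_grid):
        mask = make_sphere_mask((0.0, 12.0, 18.0), 8.0, small_grid)
        field = DisplacementField(small_grid, np.zeros(small_grid.dims + (3,)))
        np.testing.assert_array_equal(warp_mask(mask, field).occupancy, mask.occupancy)

    def test_pure_translation_shifts_against_displacement(self):
        # pull-back: u = +2 voxels along x means output voxel i reads source
        # at i+2, i.e. the mask appears shifted by -2 voxels
        geom = GridGeometry((24, 16, 12), (1.5, 2.0, 2.5))
        mask = make_sphere_mask((18.0, 15.0, 13.0), 7.0, geom)
        vec = np.zeros(geom.dims + (3,))
        vec[..., 0] = 2 * geom.spacing[0]
        warped = warp_mask(mask, DisplacementField(geom, vec))
        expected = np.zeros(geom.dims, dtype=bool)
        expected[:-2] = mask.occupancy[2:]
        np.testing.assert_array_equal(warped.occupancy, expected)
        assert warped.voxel_count == mask.voxel_count  # nothing left the grid

    def test_translation_off_grid_empties_mask(self, small_grid):
        mask = make_sphere_mask((0.0, 12.0, 18.0), 8.0, small_grid)
        vec = np.full(small_grid.dims + (3,), 1e4)
        warped = warp_mask(mask, DisplacementField(small_grid, vec))
        assert warped.voxel_count == 0

    def test_propagation_improves_dice_on_synthetic_pair(self):
        # inhale mask = exhale mask analytically displaced; warping it back
        # through the field must improve overlap with the exhale mask
        geom = GridGeometry((48, 48, 32), (1.5, 1.5, 2.5))
        shift = np.array([9.0, 4.5, 5.0])
        field_vec = np.broadcast_to(shift, geom.dims + (3,)).copy()
        field = DisplacementField(geom, field_vec)
        mask_exhale = make_sphere_mask((33.0, 33.0, 38.0), 12.0, geom, "organ")
        mask_inhale = make_sphere_mask((33.0, 33.0, 38.0) + shift, 12.0, geom, "organ")
        propagated = warp_mask(mask_inhale, field)
        assert dice(propagated, mask_exhale) > dice(mask_inhale, mask_exhale)
        assert dice(propagated, mask_exhale) > 0.95


class TestDice:
    def test_hand_counted_two_thirds(self, small_grid):
        occ_a = np.zeros(small_grid.dims, dtype=bool)
        occ_a[2, 3, 4] = occ_a[2, 3, 5] = True
        occ_b = np.zeros(small_grid.dims, dtype=bool)
        occ_b[2, 3, 4] = True
        a, b = StructureMask(small_grid, occ_a), StructureMask(small_grid, occ_b)
        assert dice(a, b) == pytest.approx(2.0 / 3.0)
        assert dice(a, b) == dice(b, a)

    def test_identical_and_disjoint(self, small_grid):
        a = make_sphere_mask((-4.0, 8.0, 12.0), 6.0, small_grid)
        b = make_sphere_mask((8.0, 20.0, 22.0), 6.0, small_grid)
        assert dice(a, a) == 1.0
        assert not np.any(a.occupancy & b.occupancy)
        assert dice(a, b) == 0.0

    def test_monotone_under_erosion_of_nested_spheres(self):
        geom = GridGeometry((40, 40, 40), (1.0, 1.0, 1.0))
        ref = make_sphere_mask((19.5, 19.5, 19.5), 15.0, geom)
        prev = 1.0
        for r in (15.0, 12.0, 9.0, 6.0, 3.0):
            d = dice(make_sphere_mask((19.5, 19.5, 19.5), r, geom), ref)
            assert d <= prev
            prev = d

    def test_two_empty_masks_undefined(self, small_grid):
        occ = np.zeros(small_grid.dims, dtype=bool)
        occ[0, 0, 0] = True  # construct non-empty, then clear
        a = StructureMask(small_grid, occ.copy())
        a.occupancy[0, 0, 0] = False
        with pytest.raises(ValueError, match="empty"):
            dice(a, a)


class TestSampleStructure:
    def test_constant_map_and_total_volume(self):
        geom = GridGeometry((24, 24, 24), (1.5, 1.5, 2.5))
        mask = make_sphere_mask((17.0, 17.0, 28.0), 10.0, geom)
        scalar = ScalarVolume(geom, np.full(geom.dims, 1.331))
        samples = sample_structure(scalar, mask)
        assert len(samples) == mask.voxel_count
        np.testing.assert_array_equal(samples.values, 1.331)
        assert samples.total_volume == pytest.approx(
            mask.voxel_count * geom.voxel_volume
        )

    def test_thousand_voxels_volume(self):
        geom = GridGeometry((16, 16, 16), (1.5, 1.5, 2.5))
        occ = np.zeros(geom.dims, dtype=bool)
        occ.flat[:1000] = True
        mask = StructureMask(geom, occ)
        samples = sample_structure(ScalarVolume(geom, np.ones(geom.dims)), mask)
        assert samples.total_volume == pytest.approx(5625.0)

    def test_identity_jacobian_samples_are_one(self, small_grid):
        field = DisplacementField(small_grid, np.zeros(small_grid.dims + (3,)))
        mask = make_sphere_mask((0.0, 12.0, 18.0), 8.0, small_grid)
        samples = sample_structure(jacobian_map(field), mask)
        np.testing.assert_array_equal(samples.values, 1.0)

    def test_exact_lookup_on_shared_grid(self, small_grid, rng):
        vals = rng.normal(size=small_grid.dims)
        mask = make_sphere_mask((0.0, 12.0, 18.0), 8.0, small_grid)
        samples = sample_structure(ScalarVolume(small_grid, vals), mask)
        np.testing.assert_allclose(
            np.sort(samples.values), np.sort(vals[mask.occupancy]), atol=1e-12
        )
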