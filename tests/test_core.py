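"""Dose-volume engine against brute-force voxel-loop oracles."""

import math

import numpy as np
import pytest

from kbpdose import (
    DoseGrid,
    EmptyStructureError,
    GeometryMismatchError,
    GridGeometry,
    StructureMask,
    centroid,
    centroid_distance,
    cumulative_dvh,
    d_at_volume_percent,
    max_dose,
    mean_dose,
    overlap_fraction,
    overlap_volume,
    structure_volume,
    sum_dose_grids,
    v_dose,
)


def mask_from_indices(geometry, indices, name="m"):
    occ = np.zeros(geometry.shape, dtype=bool)
    for idx in indices:
        occ[idx] = True
    return StructureMask(name=name, role="oar", occupancy=occ, geometry=geometry)


class TestGeometry:
    def test_voxel_volume_is_product_of_spacings(self):
        g = GridGeometry((0, 0, 0), (0.1, 0.2, 0.5), (5, 5, 5))
        assert g.voxel_volume == pytest.approx(0.01)

    @pytest.mark.parametrize("spacing", [(0, 0.1, 0.1), (0.1, -0.2, 0.1)])
    def test_non_positive_spacing_rejected(self, spacing):
        with pytest.raises(ValueError):
            GridGeometry((0, 0, 0), spacing, (5, 5, 5))

    def test_dose_grid_rejects_negative_and_nonfinite(self, small_geometry):
        bad = np.zeros(small_geometry.shape)
        bad[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            DoseGrid(small_geometry, bad)
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            DoseGrid(small_geometry, bad)

    def test_dose_shape_mismatch_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            DoseGrid(small_geometry, np.zeros((3, 3, 3)))


class TestVolumes:
    def test_thousand_voxels_at_millimetre_spacing_is_one_cc(self):
        g = GridGeometry((0, 0, 0), (0.1, 0.1, 0.1), (10, 10, 10))
        full = StructureMask("all", "oar", np.ones(g.shape, bool), g)
        assert structure_volume(full) == pytest.approx(1.0)

    def test_full_grid_at_two_millimetres_is_eight_cc(self):
        g = GridGeometry((0, 0, 0), (0.2, 0.2, 0.2), (10, 10, 10))
        full = StructureMask("all", "oar", np.ones(g.shape, bool), g)
        assert structure_volume(full) == pytest.approx(8.0)

    def test_random_mask_matches_loop_count(self, small_geometry, random_mask_factory):
        mask = random_mask_factory(seed=7)
        count = sum(
            1
            for i in range(small_geometry.shape[0])
            for j in range(small_geometry.shape[1])
            for k in range(small_geometry.shape[2])
            if mask.occupancy[i, j, k]
        )
        assert structure_volume(mask) == pytest.approx(count * small_geometry.voxel_volume)

    def test_empty_mask_raises_with_name(self, small_geometry):
        empty = StructureMask("Rectum", "oar", np.zeros(small_geometry.shape, bool), small_geometry)
        with pytest.raises(EmptyStructureError, match="Rectum"):
            structure_volume(empty)


class TestOverlap:
    def test_disjoint_masks_overlap_zero(self, small_geometry):
        a = mask_from_indices(small_geometry, [(0, 0, 0)])
        b = mask_from_indices(small_geometry, [(5, 5, 5)])
        assert overlap_volume(a, b) == 0.0
        assert overlap_fraction(a, b) == 0.0

    def test_subset_overlap_equals_subset_volume(self, random_mask_factory):
        b = random_mask_factory(seed=1, p=0.5)
        occ_a = b.occupancy.copy()
        occ_a[occ_a.cumsum().reshape(occ_a.shape) % 2 == 0] = False
        occ_a &= b.occupancy
        if not occ_a.any():
            occ_a[tuple(np.argwhere(b.occupancy)[0])] = True
        a = StructureMask("a", "oar", occ_a, b.geometry)
        assert overlap_volume(a, b) == pytest.approx(structure_volume(a))

    def test_random_masks_match_loop_and_symmetry(self, random_mask_factory):
        a = random_mask_factory(seed=2)
        b = random_mask_factory(seed=3)
        brute = sum(
            1
            for idx in np.ndindex(*a.geometry.shape)
            if a.occupancy[idx] and b.occupancy[idx]
        )
        expected = brute * a.geometry.voxel_volume
        assert overlap_volume(a, b) == pytest.approx(expected)
        assert overlap_volume(b, a) == pytest.approx(expected)
        assert overlap_volume(a, a) == pytest.approx(structure_volume(a))

    def test_identical_masks_give_100_percent(self, random_mask_factory):
        a = random_mask_factory(seed=4)
        assert overlap_fraction(a, a) == pytest.approx(100.0)

    def test_fifteen_percent_worked_arithmetic(self):
        # 200 cc OAR with 30 cc inside the target -> 15%
        g = GridGeometry((0, 0, 0), (0.2, 0.2, 0.2), (50, 50, 50))
        vv = g.voxel_volume  # 0.008 cc
        n_oar, n_in = round(200 / vv), round(30 / vv)
        occ_oar = np.zeros(g.shape, bool)
        occ_oar.ravel()[:n_oar] = True
        occ_ptv = np.zeros(g.shape, bool)
        occ_ptv.ravel()[:n_in] = True
        oar = StructureMask("oar", "oar", occ_oar, g)
        ptv = StructureMask("ptv", "target", occ_ptv, g)
        assert overlap_fraction(oar, ptv) == pytest.approx(15.0)

    def test_geometry_mismatch_rejected(self, random_mask_factory):
        a = random_mask_factory(seed=5)
        other = GridGeometry((1, 0, 0), (0.2, 0.2, 0.2), (20, 20, 20))
        b = StructureMask("b", "oar", np.ones(other.shape, bool), other)
        with pytest.raises(GeometryMismatchError):
            overlap_volume(a, b)


class TestCentroid:
    def test_single_voxel_at_origin(self, small_geometry):
        m = mask_from_indices(small_geometry, [(0, 0, 0)])
        assert centroid(m) == pytest.approx([0.0, 0.0, 0.0])

    def test_symmetric_cuboid_center(self, small_geometry):
        occ = np.zeros(small_geometry.shape, bool)
        occ[2:6, 4:10, 0:4] = True
        m = StructureMask("box", "oar", occ, small_geometry)
        # center voxel index (3.5, 6.5, 1.5) at 0.2 cm spacing
        assert centroid(m) == pytest.approx([0.7, 1.3, 0.3])

    def test_arbitrary_mask_matches_coordinate_list_average(self, random_mask_factory):
        m = random_mask_factory(seed=6)
        coords = [
            (
                m.geometry.origin[0] + i * m.geometry.spacing[0],
                m.geometry.origin[1] + j * m.geometry.spacing[1],
                m.geometry.origin[2] + k * m.geometry.spacing[2],
            )
            for (i, j, k) in np.argwhere(m.occupancy)
        ]
        expected = np.mean(coords, axis=0)
        assert centroid(m) == pytest.approx(expected)

    def test_distance_is_zero_for_same_mask(self, random_mask_factory):
        m = random_mask_factory(seed=8)
        assert centroid_distance(m, m) == 0.0

    def test_three_four_five_distance(self):
        g = GridGeometry((0, 0, 0), (1.0, 1.0, 1.0), (10, 10, 10))
        a = mask_from_indices(g, [(0, 0, 0)])
        b = mask_from_indices(g, [(3, 4, 0)])
        assert centroid_distance(a, b) == pytest.approx(5.0)
        assert centroid_distance(b, a) == pytest.approx(5.0)

    def test_random_pair_matches_norm_of_centroid_difference(self, random_mask_factory):
        a, b = random_mask_factory(seed=9), random_mask_factory(seed=10)
        diff = centroid(a) - centroid(b)
        expected = math.sqrt(sum(d * d for d in diff))
        assert centroid_distance(a, b) == pytest.approx(expected)


class TestDvh:
    def test_uniform_dose_steps_to_zero_above_level(self, small_geometry, random_mask_factory):
        mask = random_mask_factory(seed=11)
        dose = DoseGrid(small_geometry, np.full(small_geometry.shape, 50.0))
        dvh = cumulative_dvh(dose, mask, bin_width=1.0)
        vol = structure_volume(mask)
        assert dvh.cumulative_volume[0] == pytest.approx(vol)
        assert dvh.volume_at(50.0) == pytest.approx(vol)
        assert dvh.volume_at(50.9) == pytest.approx(vol)  # same bin
        assert dvh.bin_edges[-1] >= 50.0
        assert dvh.cumulative_volume[-1] == 0.0

    def test_two_voxel_structure_midpoint(self, small_geometry):
        mask = mask_from_indices(small_geometry, [(0, 0, 0), (0, 0, 1)])
        arr = np.zeros(small_geometry.shape)
        arr[0, 0, 0], arr[0, 0, 1] = 10.0, 30.0
        dose = DoseGrid(small_geometry, arr)
        dvh = cumulative_dvh(dose, mask, bin_width=1.0)
        assert dvh.volume_at(20.0) == pytest.approx(small_geometry.voxel_volume)

    def test_random_field_every_bin_matches_threshold_count(
        self, random_mask_factory, random_dose_factory
    ):
        mask = random_mask_factory(seed=12)
        dose = random_dose_factory(seed=13)
        dvh = cumulative_dvh(dose, mask, bin_width=2.5)
        voxels = [dose.dose[idx] for idx in map(tuple, np.argwhere(mask.occupancy))]
        vv = mask.geometry.voxel_volume
        for edge, vol in zip(dvh.bin_edges, dvh.cumulative_volume):
            brute = sum(1 for d in voxels if d >= edge)
            assert vol == pytest.approx(brute * vv)

    def test_monotone_non_increasing(self, random_mask_factory, random_dose_factory):
        dvh = cumulative_dvh(random_dose_factory(seed=15), random_mask_factory(seed=14))
        assert np.all(np.diff(dvh.cumulative_volume) <= 0)

    def test_bad_bin_width_rejected(self, random_mask_factory, random_dose_factory):
        with pytest.raises(ValueError):
            cumulative_dvh(random_dose_factory(seed=1), random_mask_factory(seed=1), bin_width=0)


class TestPointMetrics:
    def test_vdose_threshold_zero_is_full_volume(self, random_mask_factory, random_dose_factory):
        mask, dose = random_mask_factory(seed=16), random_dose_factory(seed=17)
        assert v_dose(dose, mask, 0.0, "percent") == pytest.approx(100.0)
        assert v_dose(dose, mask, 0.0, "cc") == pytest.approx(structure_volume(mask))

    def test_vdose_above_max_is_zero(self, random_mask_factory, random_dose_factory):
        mask, dose = random_mask_factory(seed=18), random_dose_factory(seed=19)
        assert v_dose(dose, mask, max_dose(dose, mask) + 1.0, "cc") == 0.0

    def test_vdose_random_matches_brute_count(self, random_mask_factory, random_dose_factory):
        mask, dose = random_mask_factory(seed=20), random_dose_factory(seed=21)
        voxels = dose.dose[mask.occupancy]
        for thr in (10.0, 40.0, 60.0):
            brute = sum(1 for d in voxels if d >= thr)
            assert v_dose(dose, mask, thr, "cc") == pytest.approx(
                brute * mask.geometry.voxel_volume
            )
            assert v_dose(dose, mask, thr, "percent") == pytest.approx(
                100.0 * brute / voxels.size
            )

    def test_dq_uniform_dose_is_that_dose(self, random_mask_factory, small_geometry):
        mask = random_mask_factory(seed=22)
        dose = DoseGrid(small_geometry, np.full(small_geometry.shape, 33.0))
        for q in (2, 50, 95, 98, 100):
            assert d_at_volume_percent(dose, mask, q) == 33.0

    def test_dq_rank_convention_on_1_to_100(self, small_geometry):
        # 100 voxels with doses 1..100 Gy: hottest 50% -> rank 50 descending -> 51 Gy
        indices = list(np.ndindex(*small_geometry.shape))[:100]
        mask = mask_from_indices(small_geometry, indices)
        arr = np.zeros(small_geometry.shape)
        for n, idx in enumerate(indices, start=1):
            arr[idx] = float(n)
        dose = DoseGrid(small_geometry, arr)
        assert d_at_volume_percent(dose, mask, 50) == 51.0
        assert d_at_volume_percent(dose, mask, 100) == 1.0  # minimum dose
        assert d_at_volume_percent(dose, mask, 2) == 99.0  # ceil(2) = rank 2

    def test_dq_matches_sort_oracle(self, random_mask_factory, random_dose_factory):
        mask, dose = random_mask_factory(seed=23), random_dose_factory(seed=24)
        doses = sorted((float(d) for d in dose.dose[mask.occupancy]), reverse=True)
        for q in (1, 2, 37.5, 50, 95, 98, 100):
            rank = max(1, math.ceil(q / 100 * len(doses)))
            assert d_at_volume_percent(dose, mask, q) == doses[rank - 1]

    def test_dq_monotone_non_increasing_in_q(self, random_mask_factory, random_dose_factory):
        mask, dose = random_mask_factory(seed=25), random_dose_factory(seed=26)
        values = [d_at_volume_percent(dose, mask, q) for q in np.linspace(1, 100, 40)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_mean_and_max_trivial_pairs(self, small_geometry):
        mask = mask_from_indices(small_geometry, [(0, 0, 0), (1, 0, 0)])
        arr = np.zeros(small_geometry.shape)
        arr[0, 0, 0], arr[1, 0, 0] = 10.0, 30.0
        dose = DoseGrid(small_geometry, arr)
        assert mean_dose(dose, mask) == pytest.approx(20.0)
        assert max_dose(dose, mask) == 30.0

    def test_mean_max_match_loop(self, random_mask_factory, random_dose_factory):
        mask, dose = random_mask_factory(seed=27), random_dose_factory(seed=28)
        voxels = [float(d) for d in dose.dose[mask.occupancy]]
        assert mean_dose(dose, mask) == pytest.approx(math.fsum(voxels) / len(voxels), rel=1e-12)
        assert max_dose(dose, mask) == max(voxels)

    def test_empty_mask_raises_everywhere(self, small_geometry, random_dose_factory):
        empty = StructureMask("void", "oar", np.zeros(small_geometry.shape, bool), small_geometry)
        dose = random_dose_factory(seed=29)
        for fn in (
            lambda: v_dose(dose, empty, 10),
            lambda: d_at_volume_percent(dose, empty, 50),
            lambda: mean_dose(dose, empty),
            lambda: max_dose(dose, empty),
            lambda: cumulative_dvh(dose, empty),
            lambda: centroid(empty),
        ):
            with pytest.raises(EmptyStructureError):
                fn()


class TestSumGrids:
    def test_voxelwise_addition_and_prescription_sum(self, small_geometry):
        a = DoseGrid(small_geometry, np.full(small_geometry.shape, 46.0), 46.0)
        b = DoseGrid(small_geometry, np.full(small_geometry.shape, 30.0), 30.0)
        total = sum_dose_grids([a, b])
        assert np.all(total.dose == 76.0)
        assert total.prescription_dose == 76.0
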