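import math

import numpy as np
import pytest

from upvs import (MorphCharacteristics, VesselVolume, VoxelClass, apply_threshold,
                  average_thickness, average_vessel_length, characterize,
                  classify_voxels, density_ratios, extract_segments,
                  mean_neighbor_distance, rasterize_phantom, random_tree_spec,
                  skeletonize, total_network_length)
from conftest import brute_force_neighbor_counts, skeleton_from_coords


def _classify_coords(coords, shape=(12, 12, 12)):
    sk = skeleton_from_coords(coords, shape)
    return sk, classify_voxels(sk)


class TestClassifyVoxels:
    def test_three_voxel_chain_middle_is_vessel_point(self):
        _, cls = _classify_coords([(5, 5, 4), (5, 5, 5), (5, 5, 6)])
        assert cls.labels[5, 5, 5] == VoxelClass.VESSEL
        assert cls.n_end == 2 and cls.n_vessel == 1

    def test_y_center_is_bifurcation_point(self):
        arms = ([(5, 5, 5 - i) for i in range(1, 4)]
                + [(5, 5 - i, 5 + i) for i in range(1, 4)]
                + [(5, 5 + i, 5 + i) for i in range(1, 4)])
        _, cls = _classify_coords([(5, 5, 5)] + arms)
        assert cls.labels[5, 5, 5] == VoxelClass.BIFURCATION
        assert cls.n_bif == 1 and cls.n_end == 3

    def test_isolated_and_cluster_classes(self):
        block = [(z, y, x) for z in (4, 5) for y in (4, 5) for x in (4, 5)]
        _, cls = _classify_coords(block + [(10, 10, 10)])
        assert cls.n_cluster == 8   # every cube voxel has 7 neighbours
        assert cls.n_isolated == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 15, 3))
        mask = rng.random(shape) < 0.2
        sk = skeleton_from_coords(np.argwhere(mask), shape)
        cls = classify_voxels(sk)
        oracle = brute_force_neighbor_counts(mask)
        for coord, n in oracle.items():
            assert cls.labels[coord] == min(n, 5)
        assert cls.n_total == len(oracle)


class TestExtractSegments:
    def test_open_chain_is_one_segment(self):
        sk, cls = _classify_coords([(5, 5, i) for i in range(3, 8)])
        segs = extract_segments(sk, cls)
        assert len(segs) == 1
        assert segs[0].n_interior == 3
        assert set(segs[0].boundary) == {VoxelClass.ENDPOINT}

    def test_y_with_two_vessel_arms_gives_three_segments(self):
        arms = ([(5, 5, 5 - i) for i in range(1, 3)]
                + [(5, 5 - i, 5 + i) for i in range(1, 3)]
                + [(5, 5 + i, 5 + i) for i in range(1, 3)])
        sk, cls = _classify_coords([(5, 5, 5)] + arms)
        segs = extract_segments(sk, cls)
        assert len(segs) == 3
        assert [s.n_interior for s in segs] == [1, 1, 1]

    def test_empty_skeleton_gives_no_segments(self):
        sk, cls = _classify_coords([])
        assert extract_segments(sk, cls) == []

    def test_adjacent_nodes_give_zero_interior_segment(self):
        # two endpoints directly adjacent: a 2-voxel skeleton
        sk, cls = _classify_coords([(5, 5, 5), (5, 5, 6)])
        segs = extract_segments(sk, cls)
        assert len(segs) == 1
        assert segs[0].n_interior == 0

    def test_pure_vessel_cycle_is_one_cyclic_segment(self):
        # planar diamond ring (|dy| + |dx| = 3): every voxel has exactly
        # 2 neighbours, all steps diagonal
        cy = cx = 6
        ring = sorted({(5, cy + dy, cx + dx)
                       for dy in range(-3, 4) for dx in range(-3, 4)
                       if abs(dy) + abs(dx) == 3})
        sk, cls = _classify_coords(ring)
        assert cls.n_vessel == 12
        segs = extract_segments(sk, cls)
        assert len(segs) == 1
        assert segs[0].cyclic and segs[0].n_interior == 12

    def test_every_vessel_voxel_in_exactly_one_segment(self, y_vessels):
        vv, _ = y_vessels
        sk = skeletonize(vv)
        cls = classify_voxels(sk)
        segs = extract_segments(sk, cls)
        vessel_voxels = [tuple(c) for c in np.argwhere(cls.class_mask(VoxelClass.VESSEL))]
        seen = [v for s in segs for v in s.path
                if cls.labels[v] == VoxelClass.VESSEL]
        assert sorted(seen) == sorted(vessel_voxels)


class TestLengthFormulas:
    def test_total_length_of_straight_chain(self):
        sk, cls = _classify_coords([(5, 5, i) for i in range(3, 8)])
        d = mean_neighbor_distance(sk)
        assert total_network_length(cls, d) == pytest.approx(5.0)

    def test_total_length_of_diagonal_chain(self):
        sk, cls = _classify_coords([(3 + i, 3 + i, 3 + i) for i in range(3)])
        d = mean_neighbor_distance(sk)
        assert total_network_length(cls, d) == pytest.approx(3 * math.sqrt(3))

    def test_total_length_empty(self):
        _, cls = _classify_coords([])
        assert total_network_length(cls, 1.0) == 0.0

    def test_excluded_voxels_do_not_count(self):
        _, cls = _classify_coords([(5, 5, 5), (10, 10, 10), (1, 1, 1)])
        assert cls.n_isolated == 3
        assert total_network_length(cls, 1.0) == 0.0

    def test_average_vessel_length_formula(self):
        sk, cls = _classify_coords([(5, 5, i) for i in range(3, 8)])
        segs = extract_segments(sk, cls)
        assert average_vessel_length(segs, 1.0) == pytest.approx(3.0)

    def test_average_vessel_length_of_equal_segments(self):
        arms = ([(5, 5, 5 - i) for i in range(1, 4)]
                + [(5, 5 - i, 5 + i) for i in range(1, 4)]
                + [(5, 5 + i, 5 + i) for i in range(1, 4)])
        sk, cls = _classify_coords([(5, 5, 5)] + arms)
        segs = extract_segments(sk, cls)
        assert average_vessel_length(segs, 1.0) == pytest.approx(2.0)

    def test_average_vessel_length_undefined_without_segments(self):
        with pytest.warns(UserWarning):
            assert math.isnan(average_vessel_length([], 1.0))

    def test_average_thickness_of_thin_line_is_one_voxel(self):
        vol_sel = np.zeros((7, 7, 12), bool)
        vol_sel[3, 3, 2:10] = True
        vv = VesselVolume(vol_sel, (1.0, 1.0, 1.0), 100)
        sk = skeletonize(vv)
        cls = classify_voxels(sk)
        assert average_thickness(sk, cls) == pytest.approx(1.0)

    def test_average_thickness_undefined_when_all_excluded(self):
        sk, cls = _classify_coords([(5, 5, 5)])
        with pytest.warns(UserWarning):
            assert math.isnan(average_thickness(sk, cls))


class TestCharacterize:
    def test_tube_counts(self, tube_vessels):
        vv, truth = tube_vessels
        mc = characterize(vv)
        assert (mc.n_end, mc.n_bif, mc.n_cross) == (2, 0, 0)

    def test_y_counts(self, y_vessels):
        vv, truth = y_vessels
        mc = characterize(vv)
        assert (mc.n_end, mc.n_bif) == (3, 1)

    def test_empty_selection(self):
        vv = VesselVolume(np.zeros((4, 4, 4), bool), (1, 1, 1), 100)
        mc = characterize(vv)
        assert (mc.n_end, mc.n_vessel, mc.n_bif, mc.n_cross) == (0, 0, 0, 0)
        assert mc.total_length_mm == 0.0
        assert math.isnan(mc.avg_vessel_length_mm)

    def test_tube_length_ratio_within_documented_band(self, tube_vessels):
        vv, truth = tube_vessels
        mc = characterize(vv)
        assert 0.9 <= mc.total_length_mm / truth.total_length_mm <= 1.3

    def test_spacing_scaling_scales_lengths_not_counts(self, y_vessels):
        vv, _ = y_vessels
        c = 2.0
        scaled = VesselVolume(vv.selection, tuple(c * s for s in vv.spacing), 100)
        a, b = characterize(vv), characterize(scaled)
        assert (a.n_end, a.n_vessel, a.n_bif, a.n_cross) == \
               (b.n_end, b.n_vessel, b.n_bif, b.n_cross)
        assert b.total_length_mm == pytest.approx(c * a.total_length_mm, rel=1e-9)
        assert b.avg_vessel_length_mm == pytest.approx(c * a.avg_vessel_length_mm, rel=1e-9)
        assert b.avg_thickness_mm == pytest.approx(c * a.avg_thickness_mm, rel=1e-9)

    def test_edge_sum_length_mode_close_to_true_length_on_tube(self, tube_vessels):
        vv, truth = tube_vessels
        mc = characterize(vv, length_mode="edge_sum")
        assert mc.total_length_mm == pytest.approx(truth.total_length_mm, rel=0.05)

    @pytest.mark.parametrize("seed", [11, 23])
    def test_vessel_points_are_modal_class_on_random_trees(self, seed):
        spec = random_tree_spec(seed=seed)
        vol, roi, _ = rasterize_phantom(spec)
        mc = characterize(apply_threshold(vol, roi))
        assert mc.n_vessel > max(mc.n_end, mc.n_bif, mc.n_cross)


class TestDensityRatios:
    mc = MorphCharacteristics(100, 300, 40, 10, 500.0, 3.0, 2.0)

    def test_endpoint_density_arithmetic(self):
        r = density_ratios(self.mc, pv_cm3=10.0, upvv_cm3=0.5)
        assert r.per_upvv["n_end"] == pytest.approx(200.0)
        assert r.per_pv["n_end"] == pytest.approx(10.0)

    def test_zero_pv_flags_undefined(self):
        with pytest.warns(UserWarning, match="PV"):
            r = density_ratios(self.mc, pv_cm3=0.0, upvv_cm3=0.5)
        assert not r.pv_defined
        assert all(math.isnan(v) for v in r.per_pv.values())
        assert r.upvv_defined

    def test_negative_denominator_rejected(self):
        with pytest.raises(ValueError):
            density_ratios(self.mc, pv_cm3=-1.0, upvv_cm3=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_ratio_times_denominator_recovers_numerator(self, seed):
        rng = np.random.default_rng(seed)
        mc = MorphCharacteristics(*rng.integers(1, 1000, 4),
                                  *(rng.random(3) * 100))
        pv, upvv = rng.random(2) * 50 + 0.1
        r = density_ratios(mc, pv, upvv)
        for k, v in mc.as_dict().items():
            assert r.per_pv[k] * pv == pytest.approx(v, rel=1e-9)
            assert r.per_upvv[k] * upvv == pytest.approx(v, rel=1e-9)
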