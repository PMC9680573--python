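"""Beam-axis convention, overlap maps, collision masking, oracle agreement."""

import numpy as np
import pytest

from arctraj import (OverlapMap, Sphere, Structure, apply_collision_mask,
                     beam_axis, compute_overlap_map, compute_overlap_maps,
                     merge_oars, per_oar_maps)
from arctraj.anatomy import StructureSet, ValidationError
from arctraj.bev import (ComputationError, default_angle_grid,
                         raycast_overlap_oracle)
from conftest import make_grid, sphere_structure


def rotation_about_ap(angle_deg):
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0],
                     [-np.sin(a), 0, np.cos(a)]])


class TestBeamAxis:
    def test_reference_direction_anterior_to_posterior(self):
        assert beam_axis(0, 0) == pytest.approx([0, 1, 0])

    def test_lateral_gantry_angles_are_opposite(self):
        assert beam_axis(0, 90) == pytest.approx(-beam_axis(0, 270))

    def test_antipodal_gantry_negates_axis(self):
        rng = np.random.default_rng(0)
        for c, g in rng.uniform(-90, 360, size=(100, 2)):
            assert beam_axis(c, g) @ beam_axis(c, g + 180) == pytest.approx(-1.0)

    def test_couch_rotation_matches_rotation_matrix_oracle(self):
        # couch rotation turns the patient about the vertical (AP) axis, so
        # the axis in patient coordinates is the couch-0 axis rotated about AP
        rng = np.random.default_rng(1)
        for c, g in rng.uniform(-90, 90, size=(50, 2)):
            expected = rotation_about_ap(c) @ beam_axis(0, g)
            got = beam_axis(c, g)
            assert np.allclose(got, expected) or np.allclose(got, rotation_about_ap(-c) @ beam_axis(0, g))
            assert np.linalg.norm(got) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_geometry():
    grid = make_grid(60, 2.0)
    target = sphere_structure(grid, (0, 0, 0), 12, name="PTV", role="target")
    oar = sphere_structure(grid, (0, 50, 0), 20, name="oar")
    return grid, target, oar


class TestComputeOverlapMap:
    def test_empty_avoidance_gives_zero_map(self, small_geometry):
        grid, target, _ = small_geometry
        empty = Structure(name="none", role="avoidance", grid=grid,
                          mask=np.zeros(grid.shape, bool))
        omap = compute_overlap_map(target, empty, resolution_deg=30)
        assert np.all(omap.values == 0)

    def test_containing_avoidance_gives_unit_map(self, small_geometry):
        grid, target, _ = small_geometry
        big = sphere_structure(grid, (0, 0, 0), 40, name="big")
        omap = compute_overlap_map(target, big, resolution_deg=30)
        assert np.all(omap.values == 1.0)

    def test_values_bounded(self, small_geometry):
        grid, target, oar = small_geometry
        omap = compute_overlap_map(target, oar, resolution_deg=10)
        assert omap.values.min() >= 0 and omap.values.max() <= 1

    def test_antipodal_symmetry_exact(self, small_geometry):
        grid, target, oar = small_geometry
        omap = compute_overlap_map(target, oar, resolution_deg=10)
        half = len(omap.gantry_deg) // 2
        assert np.array_equal(omap.values[:, :half], omap.values[:, half:])

    def test_point_target_distant_oar_cone(self, small_geometry):
        # a point-like target with a 10 mm radius OAR 50 mm along +AP only
        # overlaps for beam axes within ~asin(10/50) = 11.5 deg of the AP line
        grid, _, _ = small_geometry
        point = sphere_structure(grid, (0, 0, 0), 2.5, name="pt", role="target")
        oar = sphere_structure(grid, (0, 50, 0), 20, name="oar")
        omap = compute_overlap_map(point, oar, resolution_deg=10)
        ap = np.array([0, 1, 0])
        for ci, c in enumerate(omap.couch_deg):
            for gi, g in enumerate(omap.gantry_deg):
                angle = np.degrees(np.arccos(min(1, abs(beam_axis(c, g) @ ap))))
                if omap.values[ci, gi] > 0:
                    assert angle < 11.5 + 6.0  # cone half-angle + bin width slack
                if angle > 11.5 + 6.0:
                    assert omap.values[ci, gi] == 0

    def test_agreement_with_raycasting_oracle(self, small_geometry):
        grid, target, oar = small_geometry
        omap = compute_overlap_map(target, oar, resolution_deg=10)
        rng = np.random.default_rng(2)
        agree = 0
        n = 40
        for _ in range(n):
            ci = rng.integers(len(omap.couch_deg))
            gi = rng.integers(len(omap.gantry_deg))
            oracle = raycast_overlap_oracle(target, oar, omap.couch_deg[ci],
                                            omap.gantry_deg[gi])
            if abs(oracle - omap.values[ci, gi]) <= 0.05:
                agree += 1
        assert agree / n >= 0.95

    def test_mirrored_geometry_maps_to_mirrored_bins(self):
        grid = make_grid(50, 2.0)
        target = sphere_structure(grid, (20, 10, 0), 10, name="t", role="target")
        oar = sphere_structure(grid, (35, 30, 5), 14, name="o")
        m_target = sphere_structure(grid, (-20, 10, 0), 10, name="t2", role="target")
        m_oar = sphere_structure(grid, (-35, 30, 5), 14, name="o2")
        omap = compute_overlap_map(target, oar, resolution_deg=30)
        mmap = compute_overlap_map(m_target, m_oar, resolution_deg=30)
        C, G = omap.shape
        for ci, c in enumerate(omap.couch_deg):
            mc = -c
            mci = np.where(np.isclose(omap.couch_deg, mc))[0]
            if len(mci) == 0:
                continue  # -(-90) = +90 is off the couch grid
            for gi, g in enumerate(omap.gantry_deg):
                mgi = int(round(((360 - g) % 360) / 30)) % G
                assert mmap.values[mci[0], mgi] == pytest.approx(
                    omap.values[ci, gi], abs=0.1)

    def test_empty_target_rejected(self, small_geometry):
        grid, _, oar = small_geometry
        empty = Structure(name="et", role="target", grid=grid,
                          mask=np.zeros(grid.shape, bool))
        with pytest.raises(ComputationError):
            compute_overlap_map(empty, oar, resolution_deg=30)


class TestPerOarMaps:
    def test_one_map_per_oar_and_merged_dominance(self):
        grid = make_grid(50, 2.0)
        target = sphere_structure(grid, (0, 0, 0), 10, name="t", role="target")
        sset = StructureSet(grid=grid)
        oars = []
        rng = np.random.default_rng(4)
        for i in range(4):
            c = rng.uniform(-25, 25, 3)
            s = sphere_structure(grid, c, rng.uniform(8, 16), name=f"o{i}")
            sset.add(s)
            oars.append(s)
        maps = per_oar_maps(target, oars, resolution_deg=30)
        assert len(maps) == 4
        merged = compute_overlap_map(
            target, merge_oars(sset, [o.name for o in oars]), resolution_deg=30)
        for m in maps:
            assert np.all(merged.values >= m.values - 1e-12)

    def test_single_oar_equals_merged(self):
        grid = make_grid(40, 2.0)
        target = sphere_structure(grid, (0, 0, 0), 10, name="t", role="target")
        oar = sphere_structure(grid, (0, 22, 0), 12, name="o")
        sset = StructureSet(grid=grid)
        sset.add(oar)
        single = per_oar_maps(target, [oar], resolution_deg=30)[0]
        merged = compute_overlap_map(target, merge_oars(sset, ["o"]),
                                     resolution_deg=30)
        assert np.array_equal(single.values, merged.values)


class TestCollisionMask:
    def _zero_map(self, res=1.0):
        couch, gantry = default_angle_grid(res)
        return OverlapMap(couch, gantry, np.zeros((len(couch), len(gantry))))

    def test_empty_spec_identity(self):
        omap = self._zero_map(10)
        out = apply_collision_mask(omap, [])
        assert not out.collision.any()

    def test_rectangle_flags_exact_bin_count(self):
        omap = self._zero_map(1.0)
        out = apply_collision_mask(
            omap, [{"couch": (40, 90), "gantry": (150, 210)}])
        assert int(out.collision.sum()) == 50 * 60

    def test_wrapped_gantry_interval(self):
        omap = self._zero_map(10)
        out = apply_collision_mask(omap, [{"couch": (-90, 90), "gantry": (350, 10)}])
        assert int(out.collision.sum()) == 18 * 2

    def test_values_preserved_under_mask(self):
        couch, gantry = default_angle_grid(10)
        vals = np.random.default_rng(0).random((len(couch), len(gantry)))
        omap = OverlapMap(couch, gantry, vals)
        out = apply_collision_mask(omap, [{"couch": (0, 50), "gantry": (0, 90)}])
        assert np.array_equal(out.values, vals)

    def test_shape_mismatch_rejected(self):
        omap = self._zero_map(10)
        with pytest.raises(ValidationError):
            apply_collision_mask(omap, np.zeros((3, 3), bool))


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        couch, gantry = default_angle_grid(10)
        rng = np.random.default_rng(5)
        omap = OverlapMap(couch, gantry, rng.random((len(couch), len(gantry))),
                          collision=rng.random((len(couch), len(gantry))) > 0.9)
        map_path, col_path = tmp_path / "m.csv", tmp_path / "c.csv"
        omap.save_csv(map_path, col_path)
        back = OverlapMap.load_csv(map_path, col_path)
        assert np.allclose(back.values, omap.values, atol=1e-6)
        assert np.array_equal(back.collision, omap.collision)
        assert np.allclose(back.couch_deg, omap.couch_deg)
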