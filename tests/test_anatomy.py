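"""Structure model, morphology, distances, and six-class segmentation."""

import json

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import arctraj
from arctraj import (Grid, Sphere, Structure, StructureSet, classify_segment,
                     expand_prv, load_structures, merge_oars, min_distance)
from arctraj.anatomy import (FormatError, GridMismatchError, OutOfDomainError,
                             ValidationError)
from conftest import make_grid, sphere_structure


class TestVoxelization:
    @pytest.mark.parametrize("spacing,tol", [(2.0, 0.10), (1.0, 0.05), (0.5, 0.02)])
    def test_sphere_volume_converges_to_analytic(self, spacing, tol):
        grid = make_grid(15, spacing)
        s = sphere_structure(grid, (0, 0, 0), 20.0)
        analytic = np.pi * 20.0 ** 3 / 6 / 1000
        assert s.volume_cc() == pytest.approx(analytic, rel=tol)

    def test_capsule_and_ellipsoid_volumes(self):
        grid = make_grid(30, 1.0)
        cap = Structure(name="c", role="oar", grid=grid,
                        primitive=arctraj.Capsule((0, 0, -20), (0, 0, 20), 5.0))
        ell = Structure(name="e", role="oar", grid=grid,
                        primitive=arctraj.Ellipsoid((0, 0, 0), (10, 20, 5)))
        assert cap.volume_cc() == pytest.approx(cap.primitive.analytic_volume_cc(), rel=0.05)
        assert ell.volume_cc() == pytest.approx(ell.primitive.analytic_volume_cc(), rel=0.05)

    def test_nonbinary_mask_rejected(self):
        grid = make_grid(5, 1.0)
        with pytest.raises(ValidationError):
            Structure(name="bad", role="oar", grid=grid,
                      mask=np.full(grid.shape, 0.5))


class TestLoadStructures:
    def test_json_sphere_round_trip(self, tmp_path):
        doc = {"grid": {"shape": [21, 21, 21], "spacing_mm": [2, 2, 2],
                        "origin_mm": [-20, -20, -20]},
               "structures": [{"name": "PTV", "role": "target", "shape": "sphere",
                               "center_mm": [0, 0, 0], "diameter_mm": 20}]}
        path = tmp_path / "geom.json"
        path.write_text(json.dumps(doc))
        sset = load_structures(path)
        assert sset["PTV"].volume_cc() == pytest.approx(np.pi * 8 / 6 * 1000 / 1000, rel=0.10)

    def test_empty_structure_list_errors(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text(json.dumps({"grid": {"shape": [4, 4, 4], "spacing_mm": [1, 1, 1],
                                             "origin_mm": [0, 0, 0]}, "structures": []}))
        with pytest.raises(FormatError, match="no structures"):
            load_structures(path)

    def test_mismatched_nifti_grids_error(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.ones((4, 4, 4), np.uint8), np.eye(4)),
                 tmp_path / "a.nii.gz")
        nib.save(nib.Nifti1Image(np.ones((5, 5, 5), np.uint8), np.eye(4)),
                 tmp_path / "b.nii.gz")
        manifest = tmp_path / "manifest.json"
        manifest.write_text(json.dumps({"structures": [
            {"file": "a.nii.gz", "name": "a", "role": "oar"},
            {"file": "b.nii.gz", "name": "b", "role": "oar"}]}))
        with pytest.raises(GridMismatchError):
            load_structures(manifest)

    def test_unknown_role_rejected(self, tmp_path):
        doc = {"grid": {"shape": [4, 4, 4], "spacing_mm": [1, 1, 1], "origin_mm": [0, 0, 0]},
               "structures": [{"name": "x", "role": "nonsense", "shape": "sphere",
                               "center_mm": [0, 0, 0], "diameter_mm": 2}]}
        path = tmp_path / "g.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            load_structures(path)


class TestMergeOars:
    def test_disjoint_spheres_volumes_add(self):
        grid = make_grid(30, 1.0)
        d = 2 * (3 / (4 * np.pi) * 1000) ** (1 / 3)  # 1 cc sphere
        sset = StructureSet(grid=grid)
        sset.add(sphere_structure(grid, (-15, 0, 0), d, name="a"))
        sset.add(sphere_structure(grid, (15, 0, 0), d, name="b"))
        merged = merge_oars(sset, ["a", "b"])
        assert merged.role == "avoidance"
        assert merged.volume_cc() == pytest.approx(2.0, rel=0.10)

    def test_single_oar_is_identity(self):
        grid = make_grid(15, 2.0)
        sset = StructureSet(grid=grid)
        sset.add(sphere_structure(grid, (0, 0, 0), 10, name="a"))
        merged = merge_oars(sset, ["a"])
        assert np.array_equal(merged.voxelize(), sset["a"].voxelize())

    def test_duplicate_names_idempotent(self):
        grid = make_grid(15, 2.0)
        sset = StructureSet(grid=grid)
        sset.add(sphere_structure(grid, (0, 0, 0), 10, name="a"))
        once = merge_oars(sset, ["a"])
        twice = merge_oars(sset, ["a", "a"])
        assert np.array_equal(once.voxelize(), twice.voxelize())

    def test_unknown_name_is_lookup_error(self):
        sset = StructureSet(grid=make_grid(5, 1.0))
        with pytest.raises(KeyError):
            merge_oars(sset, ["ghost"])


class TestExpandPrv:
    def test_zero_margin_identity(self):
        grid = make_grid(15, 1.0)
        oar = sphere_structure(grid, (0, 0, 0), 10)
        prv = expand_prv(oar, 0.0)
        assert np.array_equal(prv.voxelize(), oar.voxelize())

    def test_two_mm_margin_matches_analytic_dilated_ball(self):
        grid = make_grid(12, 1.0)
        oar = sphere_structure(grid, (0, 0, 0), 10)  # radius 5
        prv = expand_prv(oar, 2.0)
        analytic = 4 / 3 * np.pi * 7 ** 3 / 1000
        assert prv.volume_cc() == pytest.approx(analytic, rel=0.10)

    @pytest.mark.parametrize("m1,m2", [(0, 1), (1, 3), (2, 5)])
    def test_monotone_superset(self, m1, m2):
        grid = make_grid(15, 1.0)
        oar = sphere_structure(grid, (2, -1, 3), 8)
        small = expand_prv(oar, m1).voxelize()
        big = expand_prv(oar, m2).voxelize()
        assert np.all(oar.voxelize() <= small)
        assert np.all(small <= big)

    def test_negative_margin_rejected(self):
        oar = sphere_structure(make_grid(5, 1.0), (0, 0, 0), 4)
        with pytest.raises(ValidationError):
            expand_prv(oar, -1.0)


class TestMinDistance:
    def test_overlapping_structures_zero(self):
        grid = make_grid(15, 1.0)
        a = sphere_structure(grid, (0, 0, 0), 10)
        b = sphere_structure(grid, (3, 0, 0), 10)
        assert min_distance(a, b) == 0.0

    def test_separated_spheres_analytic_gap(self):
        grid = make_grid(30, 1.0)
        a = sphere_structure(grid, (-15, 0, 0), 20)  # radius 10
        b = sphere_structure(grid, (15, 0, 0), 10)   # radius 5
        diag = np.sqrt(3)  # one voxel diagonal at 1 mm
        assert min_distance(a, b) == pytest.approx(15.0, abs=diag)

    def test_symmetry_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        grid = Grid(shape=(12, 12, 12), spacing=(1.5, 1.5, 1.5), origin=(0, 0, 0))
        for _ in range(5):
            ma = np.zeros(grid.shape, bool)
            mb = np.zeros(grid.shape, bool)
            ma[tuple(rng.integers(0, 5, (8, 3)).T)] = True
            mb[tuple(rng.integers(7, 12, (8, 3)).T)] = True
            a = Structure(name="a", role="oar", grid=grid, mask=ma)
            b = Structure(name="b", role="oar", grid=grid, mask=mb)
            brute = cdist(grid.points_mm(ma), grid.points_mm(mb)).min()
            assert min_distance(a, b) == pytest.approx(brute, abs=1e-9)
            assert min_distance(b, a) == pytest.approx(min_distance(a, b), abs=1e-9)

    def test_empty_structure_rejected(self):
        grid = make_grid(5, 1.0)
        a = sphere_structure(grid, (0, 0, 0), 4)
        empty = Structure(name="e", role="oar", grid=grid,
                          mask=np.zeros(grid.shape, bool))
        with pytest.raises(ValidationError):
            min_distance(a, empty)


class TestClassifySegment:
    @pytest.mark.parametrize("point,expected", [
        ((-10, -30, 0), 1),   # right frontal
        ((10, 30, 0), 4),     # left medial
        ((0, 20, 0), 4),      # half-open boundaries: x>=0 left, ap>=20 medial
        ((-10, 30, 0), 3),
        ((10, 65, 0), 6),
        ((-10, 65, 0), 5),
        ((10, -30, 0), 2),
    ])
    def test_rule_table(self, phantom, point, expected):
        assert classify_segment(point, phantom.brain()).id == expected

    def test_outside_brain_rejected(self, phantom):
        with pytest.raises(OutOfDomainError):
            classify_segment((0, -99, 0), phantom.brain())

    def test_mirrored_points_map_to_paired_class(self, phantom):
        brain = phantom.brain()
        pts = brain.grid.points_mm(brain.voxelize())
        rng = np.random.default_rng(0)
        pair = {1: 2, 2: 1, 3: 4, 4: 3, 5: 6, 6: 5}
        checked = 0
        for p in pts[rng.choice(len(pts), 40, replace=False)]:
            if p[0] == 0:
                continue  # midline points have no distinct mirror class
            mirrored = np.array([-p[0], p[1], p[2]])
            try:
                a = classify_segment(p, brain).id
                b = classify_segment(mirrored, brain).id
            except OutOfDomainError:
                continue
            assert b == pair[a]
            checked += 1
        assert checked > 10

    def test_partition_every_interior_point_gets_one_class(self, phantom):
        brain = phantom.brain()
        pts = brain.grid.points_mm(brain.voxelize())
        rng = np.random.default_rng(1)
        for p in pts[rng.choice(len(pts), 25, replace=False)]:
            seg = classify_segment(p, brain)
            assert 1 <= seg.id <= 6
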