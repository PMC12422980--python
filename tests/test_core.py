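"""Annotation volume, ontology, lookup, seamlessness and Dice."""

import numpy as np
import pytest

from stereoatlas import core, phantom
from stereoatlas.ontology import Ontology, OntologyError, StructureNode
from stereoatlas.volume import AnnotationVolume, BinaryMask, read_volume, write_volume


def small_ontology():
    return Ontology.from_nodes([
        StructureNode(1, "Root", "root"),
        StructureNode(11, "A", "leaf a", 1),
        StructureNode(12, "B", "leaf b", 1),
        StructureNode(21, "C", "leaf c", 1),
    ])


class TestOntology:
    def test_duplicate_acronym_rejected(self):
        with pytest.raises(OntologyError, match="duplicate acronym"):
            Ontology.from_nodes([
                StructureNode(1, "X", "x"), StructureNode(2, "X", "x2"),
            ])

    def test_cycle_rejected(self):
        # build via records so __post_init__ sees the cycle
        with pytest.raises(OntologyError):
            Ontology.from_records([
                {"id": 1, "acronym": "a", "parent_id": 2},
                {"id": 2, "acronym": "b", "parent_id": 1},
            ])

    def test_descendants_leaf_is_itself(self, world):
        nuc_a = world.ontology.id_of("NucA")
        assert world.ontology.descendants(nuc_a) == {nuc_a}

    def test_descendants_root_is_all_nodes(self, world):
        brain = world.ontology.id_of("Brain")
        assert world.ontology.descendants(brain) == set(world.ontology.nodes)

    def test_descendants_mid_level(self, world):
        ctx = world.ontology.id_of("Ctx")
        expected = {world.ontology.id_of(a) for a in ("Ctx", "L1", "L2")}
        assert world.ontology.descendants(ctx) == expected

    def test_unknown_id_raises(self, world):
        with pytest.raises(OntologyError, match="999"):
            world.ontology.descendants(999)

    def test_json_round_trip(self, world, tmp_path):
        path = tmp_path / "onto.json"
        world.ontology.save(path)
        loaded = Ontology.load(path)
        assert set(loaded.nodes) == set(world.ontology.nodes)
        assert loaded.leaves() == world.ontology.leaves()


class TestLoadAnnotation:
    @pytest.mark.parametrize("name", ["ann.nrrd", "ann.nii", "ann.nii.gz"])
    def test_round_trip_matches_generator_grid(self, world, tmp_path, name):
        path = tmp_path / name
        write_volume(path, world.annotation)
        loaded = core.load_annotation(path, world.ontology)
        assert loaded.dims == world.annotation.dims
        assert np.array_equal(loaded.data, world.annotation.data)
        assert np.allclose(loaded.voxel_size, world.annotation.voxel_size)

    def test_all_zero_volume_is_valid(self, world, tmp_path):
        path = tmp_path / "empty.nrrd"
        write_volume(path, AnnotationVolume(data=np.zeros((4, 5, 6), np.int32), voxel_size=10.0))
        loaded = core.load_annotation(path, world.ontology)
        assert loaded.label_values() == set()

    def test_unknown_label_reported_by_id(self, world, tmp_path):
        grid = np.zeros((4, 4, 4), np.int32)
        grid[1, 1, 1] = 999
        path = tmp_path / "bad.nrrd"
        write_volume(path, AnnotationVolume(data=grid, voxel_size=10.0))
        with pytest.raises(core.LabelValidationError, match="999"):
            core.load_annotation(path, world.ontology)

    def test_non_leaf_label_rejected(self, world, tmp_path):
        grid = np.full((3, 3, 3), world.ontology.id_of("Ctx"), np.int32)  # parent id
        path = tmp_path / "parent.nrrd"
        write_volume(path, AnnotationVolume(data=grid, voxel_size=10.0))
        with pytest.raises(core.LabelValidationError):
            core.load_annotation(path, world.ontology)

    def test_unreadable_file_raises_parse_error(self, world, tmp_path):
        path = tmp_path / "junk.nrrd"
        path.write_bytes(b"not an nrrd at all")
        with pytest.raises(Exception, match="NRRD"):
            core.load_annotation(path, world.ontology)


class TestStructureMask:
    def test_background_id_rejected(self, world):
        with pytest.raises(OntologyError):
            core.structure_mask(world.annotation, world.ontology, 0)

    def test_leaf_mask_matches_ellipsoid_oracle(self, world):
        """Voxel count of the NucA mask equals the direct count of voxel
        centres satisfying the ellipsoid inequality."""
        geo = world.truth.structure_geometry["NucA"]
        mask = core.structure_mask(world.annotation, world.ontology, world.ontology.id_of("NucA"))
        vs = world.config.voxel_size_um
        nx, ny, nz = world.config.dims
        cx = ((np.arange(nx) + 0.5) * vs)[:, None, None]
        cy = ((np.arange(ny) + 0.5) * vs)[None, :, None]
        cz = ((np.arange(nz) + 0.5) * vs)[None, None, :]
        c, s = np.asarray(geo["center"]), np.asarray(geo["semi"])
        inside = (((cx - c[0]) / s[0]) ** 2 + ((cy - c[1]) / s[1]) ** 2
                  + ((cz - c[2]) / s[2]) ** 2) <= 1.0
        assert mask.voxel_count == int(inside.sum())

    def test_parent_equals_union_of_children(self, world):
        onto = world.ontology
        parent = core.structure_mask(world.annotation, onto, onto.id_of("Ctx"))
        union = np.zeros(world.annotation.dims, bool)
        for child in ("L1", "L2"):
            union |= core.structure_mask(world.annotation, onto, onto.id_of(child)).data
        assert np.array_equal(parent.data, union)

    def test_hierarchy_conservation_all_parents(self, world):
        """For every non-leaf structure, mask(parent) == union of child masks."""
        onto = world.ontology
        for sid in onto.nodes:
            children = onto.children(sid)
            if not children:
                continue
            parent_mask = core.structure_mask(world.annotation, onto, sid).data
            union = np.zeros(world.annotation.dims, bool)
            # direct-label voxels of the parent itself (none in a leaf-labelled volume)
            union |= world.annotation.data == sid
            for child in children:
                union |= core.structure_mask(world.annotation, onto, child).data
            assert np.array_equal(parent_mask, union)


class TestLookup:
    def test_identity_step_equals_direct_indexing(self, world, lookup, rng):
        pts = rng.uniform(0, world.annotation.extent_um, size=(10_000, 3))
        direct = world.annotation.values_at(pts)
        via_lookup = lookup.labels_at(pts)
        assert np.array_equal(direct, via_lookup)

    def test_coarse_step_matches_cell_centres(self, world):
        coarse = core.build_lookup(world.annotation, grid_step=20.0)
        shape = np.asarray(coarse.table.shape)
        idx = np.stack(np.meshgrid(*[np.arange(0, s, 7) for s in shape], indexing="ij"),
                       axis=-1).reshape(-1, 3)
        centers = (idx + 0.5) * 20.0
        assert np.array_equal(coarse.labels_at(centers), world.annotation.values_at(centers))

    def test_step_below_voxel_size_rejected(self, world):
        with pytest.raises(ValueError, match="smaller than the voxel size"):
            core.build_lookup(world.annotation, grid_step=5.0)

    def test_out_of_volume_is_outside(self, world, lookup):
        sid, chain = core.lookup_point(lookup, (-1.0, -1.0, -1.0), world.ontology)
        assert sid == core.OUTSIDE and chain == []

    def test_ancestor_chain(self, world, lookup):
        center = world.truth.structure_geometry["NucA"]["center"]
        sid, chain = core.lookup_point(lookup, center, world.ontology)
        onto = world.ontology
        assert sid == onto.id_of("NucA")
        assert chain == [onto.id_of("NucA"), onto.id_of("Deep"), onto.id_of("Brain")]

    def test_boundary_point_goes_to_higher_voxel(self):
        grid = np.zeros((2, 1, 1), np.int32)
        grid[0] = 11
        grid[1] = 12
        onto = small_ontology()
        vol = AnnotationVolume(data=grid, voxel_size=10.0)
        lk = core.build_lookup(vol)
        # x = 10.0 is exactly the boundary between voxel 0 and voxel 1
        sid, _ = core.lookup_point(lk, (10.0, 5.0, 5.0), onto)
        assert sid == 12


class TestSeamless:
    def test_phantom_is_seamless(self, world):
        report = core.check_seamless(world.annotation, world.outline)
        assert report.seamless and report.violation_count == 0

    def test_punched_hole_is_reported_with_coordinates(self, world):
        grid = world.annotation.data.copy()
        grid[100:103, 100:103, 100:103] = 0
        broken = AnnotationVolume(data=grid, voxel_size=world.annotation.voxel_size)
        report = core.check_seamless(broken, world.outline)
        assert report.violation_count == 27
        assert {tuple(v) for v in report.example_voxels} == {
            (i, j, k) for i in range(100, 103) for j in range(100, 103) for k in range(100, 103)
        }

    def test_background_outline_is_vacuously_seamless(self, world):
        empty = BinaryMask(data=np.zeros(world.annotation.dims, bool),
                           voxel_size=world.annotation.voxel_size)
        assert core.check_seamless(world.annotation, empty).seamless

    def test_geometry_mismatch_rejected(self, world):
        other = BinaryMask(data=np.zeros((3, 3, 3), bool), voxel_size=10.0)
        with pytest.raises(ValueError, match="geometry"):
            core.check_seamless(world.annotation, other)


class TestDice:
    def make(self, grid):
        return BinaryMask(data=grid, voxel_size=10.0)

    def test_identical_nonempty_is_one(self):
        g = np.zeros((5, 5, 5), bool)
        g[1:4, 1:4, 1:4] = True
        assert core.dice(self.make(g), self.make(g)) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert core.dice(self.make(a), self.make(b)) == 0.0

    def test_shifted_cube_hand_count(self):
        """2x2x2 cube vs the same cube shifted one voxel: 4 shared voxels,
        2*4/(8+8) = 0.5."""
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0:2, 0:2, 0:2] = True
        b[1:3, 0:2, 0:2] = True
        assert core.dice(self.make(a), self.make(b)) == 0.5

    def test_both_empty_is_one(self):
        empty = np.zeros((3, 3, 3), bool)
        assert core.dice(self.make(empty), self.make(empty)) == 1.0

    def test_symmetry_and_bounds_random_masks(self, rng):
        for _ in range(20):
            a = rng.random((6, 6, 6)) < 0.3
            b = rng.random((6, 6, 6)) < 0.3
            d_ab = core.dice(a, b)
            assert d_ab == core.dice(b, a)
            assert 0.0 <= d_ab <= 1.0

    def test_mean_over_structures(self, world):
        ids = [world.ontology.id_of(a) for a in ("NucA", "NucB", "L1")]
        assert core.dice_mean(world.annotation, world.annotation, world.ontology, ids) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            core.dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))
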