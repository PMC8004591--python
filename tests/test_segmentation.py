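"""Region growing and the multi-level segmentation loop."""

import numpy as np
import pytest

from leafmorph import (
    PlantSceneSpec,
    SegmentationConfig,
    TriangleMesh,
    estimate_vertex_attributes,
    generate_plant_scene,
    multilevel_segment,
    region_growing,
    remove_non_plant,
    detect_table_plane,
    PreprocessConfig,
)

from conftest import grid_strip


def two_plates(dihedral_deg: float, joined: bool = True):
    """Two 20x10 plates meeting along the y-axis edge at a dihedral angle."""
    res = 1.0
    p1 = grid_strip(20, 10, res)
    p2 = grid_strip(20, 10, res)
    ang = np.radians(180.0 - dihedral_deg)  # fold away from coplanar
    rot = np.array([
        [np.cos(ang), 0, np.sin(ang)],
        [0, 1, 0],
        [-np.sin(ang), 0, np.cos(ang)],
    ])
    v2 = p2.vertices @ rot.T
    if joined:
        # weld the shared edge x=0 by index remapping
        ny = 11
        verts = np.vstack([p1.vertices, v2[ny:]])
        f2 = p2.faces.copy()
        f2[f2 >= ny] += p1.n_vertices - ny
        faces = np.vstack([p1.faces, f2])
        return TriangleMesh(verts, faces)
    v2 = v2 + np.array([50.0, 0.0, 0.0])
    return TriangleMesh(np.vstack([p1.vertices, v2]),
                        np.vstack([p1.faces, p2.faces + p1.n_vertices]))


class TestRegionGrowing:
    def test_single_flat_plate_one_cluster(self):
        mesh = grid_strip(20, 10, 1.0)
        fld = estimate_vertex_attributes(mesh, n_p=20)
        clusters = region_growing(mesh, fld, eps_a=5.0, eps_b=0.05,
                                  min_cluster_vertices=10)
        assert len(clusters) == 1
        assert len(clusters[0].vertex_ids) == mesh.n_vertices

    def test_disconnected_patches_stay_separate(self):
        mesh = two_plates(0.0, joined=False)
        fld = estimate_vertex_attributes(mesh, n_p=20)
        clusters = region_growing(mesh, fld, eps_a=90.0, eps_b=0.3,
                                  min_cluster_vertices=10)
        assert len(clusters) == 2

    def test_dihedral_threshold_crossing(self):
        # plates folded 60 degrees out of plane, with analytically exact
        # plate normals: the single admission step across the crease sees
        # the full 60 degree jump
        from leafmorph import VertexField

        mesh = two_plates(60.0)
        ang = np.radians(60.0)
        n_a = np.array([0.0, 0.0, 1.0])
        n_b = np.array([-np.sin(ang), 0.0, np.cos(ang)])
        on_b = mesh.vertices[:, 0] < -1e-9  # folded plate has x < 0
        normals = np.where(on_b[:, None], n_b, n_a)
        fld = VertexField(normals=normals, curvature=np.zeros(mesh.n_vertices),
                          smoothness=np.zeros(mesh.n_vertices))
        tight = region_growing(mesh, fld, eps_a=30.0, eps_b=0.3,
                               min_cluster_vertices=10)
        loose = region_growing(mesh, fld, eps_a=89.0, eps_b=0.3,
                               min_cluster_vertices=10)
        assert len(tight) == 2
        assert len(loose) == 1

    def test_clusters_vertex_disjoint(self):
        mesh = two_plates(60.0)
        fld = estimate_vertex_attributes(mesh, n_p=12)
        clusters = region_growing(mesh, fld, eps_a=30.0, eps_b=0.3,
                                  min_cluster_vertices=5)
        seen = set()
        for c in clusters:
            ids = set(c.vertex_ids.tolist())
            assert not (ids & seen)
            seen |= ids

    def test_determinism(self):
        mesh = two_plates(45.0)
        fld = estimate_vertex_attributes(mesh, n_p=12)
        r1 = region_growing(mesh, fld, eps_a=20.0, eps_b=0.1, min_cluster_vertices=5)
        r2 = region_growing(mesh, fld, eps_a=20.0, eps_b=0.1, min_cluster_vertices=5)
        assert len(r1) == len(r2)
        for c1, c2 in zip(r1, r2):
            assert (c1.vertex_ids == c2.vertex_ids).all()


@pytest.fixture(scope="module")
def no_occlusion_run():
    spec = PlantSceneSpec(n_leaves=6, occlusion_level="none", rng_seed=7,
                          mesh_resolution_mm=1.2)
    scene, ledger = generate_plant_scene(spec)
    plane = detect_table_plane(scene, PreprocessConfig(rng_seed=0))
    plant = remove_non_plant(scene, plane)
    report = multilevel_segment(plant, SegmentationConfig())
    return plant, ledger, report


class TestMultilevel:
    def test_six_leaf_plant_recovers_six_typical(self, no_occlusion_run):
        plant, ledger, report = no_occlusion_run
        assert len(report.typical_leaves) == 6
        # ledger match: each typical cluster lies >=90% inside one true leaf
        src = plant.source_vertex_indices
        for cluster in report.typical_leaves:
            scene_ids = set(src[cluster.vertex_ids].tolist())
            best = max(
                len(scene_ids & ledger.leaf_vertex_sets[rec.leaf_id])
                for rec in ledger.leaves
            )
            assert best / len(scene_ids) >= 0.9

    def test_typical_leaves_vertex_disjoint(self, no_occlusion_run):
        _, _, report = no_occlusion_run
        seen = set()
        for c in report.typical_leaves:
            ids = set(c.vertex_ids.tolist())
            assert not (ids & seen)
            seen |= ids

    def test_every_typical_passes_final_model(self, no_occlusion_run):
        from leafmorph import detect_typical

        _, _, report = no_occlusion_run
        assert report.final_model is not None
        for c in report.typical_leaves:
            assert detect_typical(c.traits, report.final_model).is_typical

    def test_threshold_schedule_strictly_decreasing(self, no_occlusion_run):
        _, _, report = no_occlusion_run
        eps_a = [r.eps_a for r in report.levels]
        eps_b = [r.eps_b for r in report.levels]
        assert all(x > y for x, y in zip(eps_a, eps_a[1:]))
        assert all(x > y for x, y in zip(eps_b, eps_b[1:]))

    def test_terminates_within_thirty_levels(self, no_occlusion_run):
        _, _, report = no_occlusion_run
        assert report.levels_run <= 30

    def test_termination_bound_on_hard_input(self):
        # heavily damaged plant exercises many levels but never exceeds 30
        spec = PlantSceneSpec(n_leaves=8, occlusion_level="heavy", rng_seed=3,
                              mesh_resolution_mm=1.5, dropout_fraction=0.2)
        scene, _ = generate_plant_scene(spec)
        plane = detect_table_plane(scene, PreprocessConfig(rng_seed=0))
        plant = remove_non_plant(scene, plane)
        report = multilevel_segment(plant, SegmentationConfig())
        assert report.levels_run <= 30

    def test_newborn_leaf_excluded_by_size_band(self):
        spec = PlantSceneSpec(n_leaves=6, n_newborn=1, occlusion_level="none",
                              rng_seed=7, mesh_resolution_mm=1.2)
        scene, ledger = generate_plant_scene(spec)
        plane = detect_table_plane(scene, PreprocessConfig(rng_seed=0))
        plant = remove_non_plant(scene, plane)
        report = multilevel_segment(plant, SegmentationConfig())
        assert len(report.typical_leaves) == 6
        newborn = next(r for r in ledger.leaves if r.is_newborn)
        src = plant.source_vertex_indices
        for cluster in report.typical_leaves:
            scene_ids = set(src[cluster.vertex_ids].tolist())
            olap = len(scene_ids & ledger.leaf_vertex_sets[newborn.leaf_id])
            assert olap / len(scene_ids) < 0.5
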