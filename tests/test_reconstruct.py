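"""Sheet reconstruction, repair, orientation and polarity assignment."""

import numpy as np
import pytest

from epifold.io import CellRecord
from epifold.reconstruct import (
    ConfigurationError,
    PolarityField,
    ReconstructionError,
    SheetMesh,
    assign_polarity,
    detect_and_repair_holes,
    orient_faces,
    reconstruct_crust,
    refine_mesh,
)
from oracles import check_mesh_consistency


def _grid_points(n=10, step=1.0):
    gx, gy = np.meshgrid(np.arange(n) * step, np.arange(n) * step)
    return np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])


def _pipeline(points, labels=None):
    mesh = reconstruct_crust(points, labels)
    mesh = refine_mesh(mesh)
    mesh = detect_and_repair_holes(mesh)
    return orient_faces(mesh)


def _cells_at(points, labels=None):
    labels = labels if labels is not None else range(1, len(points) + 1)
    return [
        CellRecord(label=int(l), centroid=np.asarray(p, float), voxel_count=1)
        for l, p in zip(labels, points)
    ]


class TestCrust:
    def test_sphere_normals_radial(self, sphere_points):
        mesh = _pipeline(sphere_points)
        assert mesh.is_manifold()
        vn = mesh.vertex_normals()
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        ang = np.degrees(
            np.arccos(np.clip(np.abs(np.einsum("ij,ij->i", vn, radial)), -1, 1))
        )
        assert ang.max() < 5.0
        assert len(mesh.boundary_loops()) == 0  # closed sample -> closed crust

    def test_planar_grid(self):
        mesh = _pipeline(_grid_points())
        fn = mesh.face_normals()
        assert np.allclose(np.abs(fn[:, 2]), 1.0, atol=1e-9)
        assert mesh.is_manifold()
        assert len(mesh.boundary_loops()) == 1  # single outer rim, no holes

    def test_all_centroids_are_vertices(self, sphere_points):
        mesh = reconstruct_crust(sphere_points, labels=np.arange(1, 201))
        assert len(mesh.vertices) == len(sphere_points)
        assert np.array_equal(mesh.vertex_labels, np.arange(1, 201))

    def test_too_few_points(self):
        with pytest.raises(ReconstructionError):
            reconstruct_crust(np.eye(3))

    def test_collinear_points(self):
        pts = np.outer(np.arange(8.0), [1.0, 2.0, 0.5])
        with pytest.raises(ReconstructionError, match="collinear"):
            reconstruct_crust(pts)


class TestRefine:
    def test_duplicate_face_removed(self):
        mesh = reconstruct_crust(_grid_points(5))
        nv, nf = len(mesh.vertices), len(mesh.faces)
        mesh.faces = np.vstack([mesh.faces, mesh.faces[0][None, :]])
        out = refine_mesh(mesh)
        assert (len(out.vertices), len(out.faces)) == (nv, nf)
        assert any("duplicate" in line for line in out.repair_log)

    def test_duplicate_vertex_merged(self):
        mesh = reconstruct_crust(_grid_points(5))
        nv = len(mesh.vertices)
        mesh.vertices = np.vstack([mesh.vertices, mesh.vertices[0][None, :]])
        mesh.vertex_labels = np.concatenate([mesh.vertex_labels, [999]])
        out = refine_mesh(mesh)
        assert len(out.vertices) == nv

    def test_nonmanifold_fin_resolved(self):
        """Three faces on one edge (a fin): result must be manifold."""
        mesh = reconstruct_crust(_grid_points(5))
        uniq, counts = mesh.edge_face_counts()
        interior = uniq[counts == 2][0]
        apex = mesh.vertices[interior].mean(axis=0) + [0, 0, 1.0]
        ia = len(mesh.vertices)
        mesh.vertices = np.vstack([mesh.vertices, apex])
        mesh.vertex_labels = np.concatenate([mesh.vertex_labels, [-1]])
        mesh.faces = np.vstack([mesh.faces, [interior[0], interior[1], ia]])
        assert not mesh.is_manifold()
        out = refine_mesh(mesh)
        assert out.is_manifold()

    def test_clean_mesh_unchanged(self):
        mesh = refine_mesh(reconstruct_crust(_grid_points(6)))
        again = refine_mesh(mesh)
        assert np.array_equal(again.faces, mesh.faces)
        assert np.array_equal(again.vertices, mesh.vertices)
        assert again.repair_log == mesh.repair_log  # no new entries


class TestHoles:
    def test_interior_hole_detected_and_filled(self):
        mesh = refine_mesh(reconstruct_crust(_grid_points(8)))
        boundary_v = set(int(x) for e in mesh.boundary_edges() for x in e)
        interior = [
            fi
            for fi, f in enumerate(mesh.faces)
            if not (set(int(v) for v in f) & boundary_v)
        ]
        mesh.faces = np.delete(mesh.faces, interior[0], axis=0)
        assert len(mesh.boundary_loops()) == 2
        out = detect_and_repair_holes(mesh)
        assert len(out.warnings) == 1
        assert len(out.boundary_loops()) == 1
        assert out.hole_vertices  # rim recorded for downstream flags

    def test_intact_sheet_is_noop(self):
        mesh = refine_mesh(reconstruct_crust(_grid_points(8)))
        out = detect_and_repair_holes(mesh)
        assert np.array_equal(out.faces, mesh.faces)
        assert out.warnings == []

    def test_sphere_patch_hole_filled_with_good_normals(self, sphere_points):
        mesh = refine_mesh(reconstruct_crust(sphere_points))
        seed_v = 0
        patch = [fi for fi, f in enumerate(mesh.faces) if seed_v in f][:5]
        mesh.faces = np.delete(mesh.faces, patch, axis=0)
        out = orient_faces(detect_and_repair_holes(mesh))
        assert len(out.warnings) >= 1
        assert len(out.boundary_loops()) == 0
        vn = out.vertex_normals()
        region = sorted(out.hole_vertices)  # rim of the filled hole
        radial = out.vertices[region]
        radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
        ang = np.degrees(
            np.arccos(np.clip(np.abs(np.einsum("ij,ij->i", vn[region], radial)), -1, 1))
        )
        assert ang.max() < 15.0


class TestOrient:
    def test_consistent_mesh_unchanged(self):
        mesh = orient_faces(refine_mesh(reconstruct_crust(_grid_points(6))))
        again = orient_faces(mesh)
        assert np.array_equal(again.faces, mesh.faces)

    def test_single_flipped_face_rewound(self):
        mesh = orient_faces(refine_mesh(reconstruct_crust(_grid_points(6))))
        mesh.faces[3] = mesh.faces[3][::-1]
        out = orient_faces(mesh)
        check_mesh_consistency(out)

    def test_disconnected_patches_warn(self):
        a = _grid_points(5)
        b = _grid_points(5) + [100.0, 0.0, 0.0]
        ma = refine_mesh(reconstruct_crust(a))
        mb = refine_mesh(reconstruct_crust(b))
        merged = SheetMesh(
            vertices=np.vstack([ma.vertices, mb.vertices]),
            faces=np.vstack([ma.faces, mb.faces + len(ma.vertices)]),
            vertex_labels=np.concatenate([ma.vertex_labels, mb.vertex_labels + 100]),
        )
        merged.faces[1] = merged.faces[1][::-1]  # perturb one winding
        out = orient_faces(merged)
        check_mesh_consistency(out)
        assert any("components" in w for w in out.warnings)


class TestAssignPolarity:
    def test_sphere_in_points_inward(self, sphere_points):
        mesh = _pipeline(sphere_points)
        cells = _cells_at(mesh.vertices, mesh.vertex_labels)
        pf = assign_polarity(mesh, cells, "in")
        assert np.allclose(pf.convergent_point, 0.0, atol=2.0)
        for cell in cells:
            n = pf[cell.label]
            assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-9)
            assert np.dot(pf.convergent_point - cell.centroid, n) > 0

    def test_in_out_antisymmetry(self, sphere_points):
        mesh = _pipeline(sphere_points)
        cells = _cells_at(mesh.vertices, mesh.vertex_labels)
        pin = assign_polarity(mesh, cells, "in")
        pout = assign_polarity(mesh, cells, "out")
        for lab in pin.normals:
            assert pin[lab] == pytest.approx(-pout[lab], abs=1e-12)

    def test_missing_mode_is_configuration_error(self, sphere_points):
        mesh = _pipeline(sphere_points)
        with pytest.raises(ConfigurationError):
            assign_polarity(mesh, _cells_at(mesh.vertices, mesh.vertex_labels), None)

    def test_pre_assigned_used_verbatim_after_normalization(self, sphere_points):
        mesh = _pipeline(sphere_points)
        cells = _cells_at(mesh.vertices, mesh.vertex_labels)
        pre = {c.label: np.array([0.0, 0.0, 2.0]) for c in cells}
        pf = assign_polarity(mesh, cells, "in", pre_assigned=pre)
        for lab in pre:
            assert pf[lab] == pytest.approx([0.0, 0.0, 1.0])
            assert "pre-assigned" in pf.flags[lab]

    def test_pre_assigned_zero_vector_rejected(self, sphere_points):
        mesh = _pipeline(sphere_points)
        cells = _cells_at(mesh.vertices, mesh.vertex_labels)
        pre = {cells[0].label: np.zeros(3)}
        with pytest.raises(ConfigurationError):
            assign_polarity(mesh, cells, "in", pre_assigned=pre)

    def test_manual_flip_cells(self, sphere_points):
        mesh = _pipeline(sphere_points)
        cells = _cells_at(mesh.vertices, mesh.vertex_labels)
        base = assign_polarity(mesh, cells, "in")
        flipped = assign_polarity(mesh, cells, "in", flip_cells=[cells[0].label])
        assert flipped[cells[0].label] == pytest.approx(-base[cells[0].label])
        assert "manual-flip" in flipped.flags[cells[0].label]

    def test_dropped_centroid_gets_interpolated_polarity(self, sphere_points):
        mesh = _pipeline(sphere_points)
        cells = _cells_at(mesh.vertices, mesh.vertex_labels)
        extra = CellRecord(label=999, centroid=np.array([0.0, 0.0, 51.0]), voxel_count=1)
        pf = assign_polarity(mesh, cells + [extra], "out")
        assert "no-vertex" in pf.flags[999]
        assert np.linalg.norm(pf[999]) == pytest.approx(1.0, abs=1e-9)
        # near the north pole of the sphere the outward normal is ~ +z
        assert pf[999][2] > 0.9

    def test_determinism(self, sphere_points):
        m1 = _pipeline(sphere_points)
        m2 = _pipeline(sphere_points)
        assert np.array_equal(m1.faces, m2.faces)
        c1 = _cells_at(m1.vertices, m1.vertex_labels)
        p1 = assign_polarity(m1, c1, "in")
        p2 = assign_polarity(m2, c1, "in")
        for lab in p1.normals:
            assert np.array_equal(p1[lab], p2[lab])
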