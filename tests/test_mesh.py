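"""Mesh data model, STL round-trips, cleaning and rigid transforms."""

import struct

import numpy as np
import pytest

from maskfit import (
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    clean_mesh,
    pre_rotate,
    read_stl,
    vertex_area_weights,
    write_stl,
)
from maskfit.mesh import EmptyMeshError, MeshFormatError

from conftest import grid_mesh, unit_cube_mesh


class TestSurfaceMesh:
    def test_rejects_out_of_range_faces(self):
        with pytest.raises(ValueError, match="out of range"):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 3]]))

    def test_rejects_non_finite_vertices(self):
        vertices = np.zeros((3, 3))
        vertices[1, 2] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            SurfaceMesh(vertices, np.array([[0, 1, 2]]))


class TestSTLRoundTrip:
    def test_cube_welds_to_eight_vertices(self, tmp_path):
        cube = unit_cube_mesh()
        path = tmp_path / "cube.stl"
        write_stl(cube, path)
        back = read_stl(path)
        assert back.n_faces == 12
        assert back.n_vertices == 8

    @pytest.mark.parametrize("dialect", ["binary", "ascii"])
    def test_round_trip_preserves_geometry(self, tmp_path, dialect):
        mesh = grid_mesh(6, 6, z=1.5)
        path = tmp_path / f"grid_{dialect}.stl"
        write_stl(mesh, path, dialect=dialect)
        back = read_stl(path)
        assert back.n_faces == mesh.n_faces
        # vertex order may change through facet serialization; compare sets
        orig = np.array(sorted(map(tuple, np.round(mesh.vertices, 5))))
        new = np.array(sorted(map(tuple, np.round(back.vertices, 5))))
        np.testing.assert_allclose(orig, new, atol=1e-5)

    def test_ascii_and_binary_dialects_agree(self, tmp_path):
        mesh = grid_mesh(5, 5, z=-2.0)
        pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
        write_stl(mesh, pa, dialect="ascii")
        write_stl(mesh, pb, dialect="binary")
        ma, mb = read_stl(pa), read_stl(pb)
        assert ma.n_vertices == mb.n_vertices
        sa = np.array(sorted(map(tuple, np.round(ma.vertices, 5))))
        sb = np.array(sorted(map(tuple, np.round(mb.vertices, 5))))
        np.testing.assert_allclose(sa, sb, atol=1e-5)

    def test_binary_facet_count_field(self, tmp_path):
        square = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]]),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        path = tmp_path / "square.stl"
        write_stl(square, path)
        raw = path.read_bytes()
        (count,) = struct.unpack("<I", raw[80:84])
        assert count == 2

    def test_empty_mesh_not_written(self, tmp_path):
        empty = SurfaceMesh(np.zeros((3, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(EmptyMeshError):
            write_stl(empty, tmp_path / "empty.stl")

    def test_truncated_binary_reports_offset(self, tmp_path):
        cube = unit_cube_mesh()
        path = tmp_path / "cube.stl"
        write_stl(cube, path)
        truncated = tmp_path / "trunc.stl"
        truncated.write_bytes(path.read_bytes()[:-37])
        with pytest.raises(MeshFormatError, match="byte offset"):
            read_stl(truncated)


class TestCleanMesh:
    def test_idempotent_on_clean_mesh(self):
        mesh = grid_mesh(5, 5)
        once = clean_mesh(mesh)
        twice = clean_mesh(once)
        assert once.n_faces == mesh.n_faces
        np.testing.assert_allclose(once.vertices, twice.vertices)
        np.testing.assert_array_equal(once.faces, twice.faces)

    def test_removes_duplicate_face(self):
        mesh = grid_mesh(4, 4)
        dup = SurfaceMesh(
            mesh.vertices, np.vstack([mesh.faces, mesh.faces[3]])
        )
        cleaned = clean_mesh(dup)
        assert cleaned.n_faces == mesh.n_faces

    def test_removes_tiny_floating_component(self):
        mesh = grid_mesh(8, 8, extent=20.0)  # area 400
        extra_v = np.array(
            [[100, 100, 0], [100.1, 100, 0], [100, 100.1, 0.0]]
        )
        combined = SurfaceMesh(
            np.vstack([mesh.vertices, extra_v]),
            np.vstack([mesh.faces, [[64, 65, 66]]]),
        )
        cleaned = clean_mesh(combined, min_component_fraction=0.01)
        assert cleaned.n_faces == mesh.n_faces
        assert cleaned.n_vertices == mesh.n_vertices

    def test_all_degenerate_raises(self):
        bad = SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))
        with pytest.raises(EmptyMeshError):
            clean_mesh(bad)


class TestRigidTransform:
    def test_rejects_reflection(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_compose_then_inverse_is_identity(self):
        T = RigidTransform.from_axis_angle("z", 37.0, (1.0, -2.0, 3.0))
        assert T.compose(T.inverse()).is_identity(atol=1e-12)

    def test_pre_rotate_analytic(self):
        mesh = SurfaceMesh(np.array([[1.0, 0, 0]]), np.zeros((0, 3), int))
        rotated = pre_rotate(mesh, "z", 90.0)
        np.testing.assert_allclose(
            rotated.vertices[0], [0, 1, 0], atol=1e-12
        )

    def test_pre_rotate_zero_angle_is_identity(self):
        mesh = grid_mesh(4, 4, z=2.0)
        np.testing.assert_allclose(
            pre_rotate(mesh, "x", 0.0).vertices, mesh.vertices
        )

    def test_two_quarter_turns_equal_half_turn(self):
        mesh = grid_mesh(4, 4, z=1.0)
        twice = pre_rotate(pre_rotate(mesh, "x", 90.0), "x", 90.0)
        once = pre_rotate(mesh, "x", 180.0)
        np.testing.assert_allclose(twice.vertices, once.vertices, atol=1e-12)

    def test_apply_transform_is_isometry(self):
        mesh = grid_mesh(5, 5, z=3.0)
        T = RigidTransform.from_axis_angle("y", 25.0, (4.0, 5.0, -6.0))
        moved = apply_transform(mesh, T)
        rng = np.random.default_rng(0)
        i, j = rng.integers(0, mesh.n_vertices, size=(2, 50))
        before = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
        after = np.linalg.norm(moved.vertices[i] - moved.vertices[j], axis=1)
        np.testing.assert_allclose(before, after, atol=1e-9)

    def test_transform_round_trip(self):
        mesh = grid_mesh(5, 5)
        T = RigidTransform.from_axis_angle("x", 80.0, (5.0, 2.0, -3.0))
        back = apply_transform(apply_transform(mesh, T), T.inverse())
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-9)

    def test_pure_translation_shifts_centroid(self):
        mesh = grid_mesh(6, 6)
        T = RigidTransform(np.eye(3), np.array([5.0, 2.0, -3.0]))
        moved = apply_transform(mesh, T)
        np.testing.assert_allclose(
            moved.centroid - mesh.centroid, [5.0, 2.0, -3.0], atol=1e-12
        )


class TestVertexAreaWeights:
    def test_single_triangle_splits_equally(self):
        # right triangle with legs 4 and 3: area 6
        tri = SurfaceMesh(
            np.array([[0, 0, 0], [4, 0, 0], [0, 3, 0.0]]),
            np.array([[0, 1, 2]]),
        )
        np.testing.assert_allclose(vertex_area_weights(tri), [2.0, 2.0, 2.0])

    def test_weights_conserve_total_area(self):
        mesh = grid_mesh(9, 9, extent=1.0)  # unit square
        assert vertex_area_weights(mesh).sum() == pytest.approx(1.0, rel=1e-9)

    def test_sphere_area_converges_with_refinement(self):
        import trimesh

        areas = []
        for sub in (2, 4):
            ico = trimesh.creation.icosphere(subdivisions=sub, radius=10.0)
            mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
            areas.append(vertex_area_weights(mesh).sum())
        exact = 4 * np.pi * 100.0
        assert abs(areas[1] - exact) < abs(areas[0] - exact)
        assert areas[1] == pytest.approx(exact, rel=5e-3)
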