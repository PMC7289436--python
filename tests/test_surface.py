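"""Surface I/O, repair, vertex frames, neighbor pairs and geodesics."""

import struct

import numpy as np
import pytest

import ephapy as ep
from ephapy.surface import SurfaceFormatError

from conftest import random_rotation

TETRA_V = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
TETRA_F = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


class TestIO:
    def test_minimal_ply_roundtrip(self, tmp_path):
        path = tmp_path / "tri.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 3\n"
            "property float x\nproperty float y\nproperty float z\n"
            "element face 1\nproperty list uchar int vertex_indices\n"
            "end_header\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n"
        )
        mesh = ep.read_surface(path)
        assert mesh.n_vertices == 3 and mesh.n_faces == 1

    @pytest.mark.parametrize("fmt,ext", [("ply", ".ply"), ("off", ".off"), ("freesurfer", ".surf")])
    def test_write_read_roundtrip(self, tmp_path, fmt, ext):
        mesh = ep.SurfaceMesh(TETRA_V, TETRA_F, name="tetra")
        path = tmp_path / f"tetra{ext}"
        ep.write_surface(mesh, path, format=fmt)
        back = ep.read_surface(path, format=fmt)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, mesh.faces)

    def test_freesurfer_dialect_hex_layout(self, tmp_path):
        """Independent byte-level parse of the triangle-surface dialect:
        3-byte magic 0xFFFFFE, creation comment ending in two newlines,
        big-endian int32 vertex/face counts, float32 coordinates."""
        path = tmp_path / "tetra.surf"
        ep.write_surface(ep.SurfaceMesh(TETRA_V, TETRA_F), path, format="freesurfer")
        raw = path.read_bytes()
        assert raw[:3] == b"\xff\xff\xfe"
        end = raw.index(b"\n\n") + 2
        vnum, fnum = struct.unpack(">ii", raw[end:end + 8])
        assert (vnum, fnum) == (4, 4)
        coords = struct.unpack(f">{vnum * 3}f", raw[end + 8:end + 8 + vnum * 12])
        np.testing.assert_allclose(np.array(coords).reshape(4, 3), TETRA_V, atol=1e-7)

    def test_bad_magic_names_offset(self, tmp_path):
        path = tmp_path / "junk.surf"
        path.write_bytes(b"\x00\x01\x02garbage")
        with pytest.raises(SurfaceFormatError, match="byte offset 0"):
            ep.read_surface(path, format="freesurfer")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ep.read_surface(tmp_path / "nope.ply")

    def test_empty_mesh_rejected(self):
        with pytest.raises(SurfaceFormatError):
            ep.SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))

    @pytest.mark.parametrize("fmt,ext", [("curv", ".curv"), ("csv", ".csv")])
    def test_vertex_map_roundtrip(self, tmp_path, fmt, ext):
        values = np.array([1.0, -2.5, np.nan, 3.25])
        path = tmp_path / f"map{ext}"
        ep.write_vertex_map(path, values, format=fmt, n_vertices=4)
        back = ep.read_vertex_map(path, format=fmt, n_vertices=4)
        np.testing.assert_array_equal(np.isnan(back), np.isnan(values))
        np.testing.assert_allclose(back[~np.isnan(values)], values[~np.isnan(values)], rtol=1e-7)

    def test_constant_map_roundtrip_exact(self, tmp_path):
        path = tmp_path / "c.csv"
        ep.write_vertex_map(path, np.ones(5), format="csv")
        np.testing.assert_array_equal(ep.read_vertex_map(path, format="csv"), np.ones(5))

    def test_map_length_mismatch(self, tmp_path):
        with pytest.raises(ValueError, match="vertex count"):
            ep.write_vertex_map(tmp_path / "m.csv", np.ones(3), format="csv", n_vertices=5)

    def test_curv_magic_checked(self, tmp_path):
        path = tmp_path / "bad.curv"
        path.write_bytes(b"\x00\x00\x00rest")
        with pytest.raises(SurfaceFormatError, match="byte offset 0"):
            ep.read_vertex_map(path, format="curv")


class TestRepair:
    def test_duplicate_face_removed(self):
        mesh = ep.SurfaceMesh(TETRA_V, np.vstack([TETRA_F, TETRA_F[:1]]))
        assert ep.repair_mesh(mesh).n_faces == 4

    def test_clean_mesh_unchanged_and_idempotent(self, sphere10):
        mesh, _ = sphere10
        once = ep.repair_mesh(mesh)
        twice = ep.repair_mesh(once)
        np.testing.assert_array_equal(once.vertices, mesh.vertices)
        np.testing.assert_array_equal(once.faces, mesh.faces)
        np.testing.assert_array_equal(twice.faces, once.faces)

    def test_coincident_vertices_merged(self):
        v = np.vstack([TETRA_V, TETRA_V[0]])  # vertex 4 duplicates vertex 0
        f = np.array([[4, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        repaired = ep.repair_mesh(ep.SurfaceMesh(v, f))
        assert repaired.n_vertices == 4
        assert repaired.n_faces == 4

    def test_degenerate_face_removed(self):
        f = np.vstack([TETRA_F, [[1, 1, 2]]])
        assert ep.repair_mesh(ep.SurfaceMesh(TETRA_V, f)).n_faces == 4

    def test_unrepairable_raises(self):
        mesh = ep.SurfaceMesh(TETRA_V, np.array([[0, 0, 1]]))
        with pytest.raises(ValueError, match="unrepairable"):
            ep.repair_mesh(mesh)


class TestVertexFrame:
    def test_sphere_normals_radial_and_area(self):
        mesh = ep.make_sphere(1.0, subdivisions=7)
        frame = ep.compute_vertex_frame(mesh, orientation="outward")
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        assert np.max(np.linalg.norm(frame.normals - radial, axis=1)) < 1e-3
        assert abs(frame.areas.sum() - 4 * np.pi) / (4 * np.pi) < 0.01

    def test_flat_sheet_normals(self, flat_sheet):
        mesh, frame = flat_sheet
        np.testing.assert_allclose(frame.normals, np.tile([0.0, 0.0, 1.0], (mesh.n_vertices, 1)),
                                   atol=1e-12)

    def test_vertex_areas_conserve_face_area(self, sulcus25):
        mesh, frame, _ = sulcus25
        assert abs(frame.areas.sum() - mesh.total_area()) <= 1e-6 * mesh.total_area()

    def test_outward_flips_inverted_closed_mesh(self, sphere10):
        mesh, frame = sphere10
        flipped = ep.SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1])
        frame2 = ep.compute_vertex_frame(flipped, orientation="outward")
        np.testing.assert_allclose(frame2.normals, frame.normals, atol=1e-12)

    def test_open_mesh_outward_warns(self, flat_sheet):
        mesh, _ = flat_sheet
        with pytest.warns(UserWarning, match="open mesh"):
            ep.compute_vertex_frame(mesh, orientation="outward")

    def test_rigid_motion_invariance(self, sulcus25, rng):
        mesh, frame, _ = sulcus25
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        moved = ep.SurfaceMesh(mesh.vertices @ R.T + t, mesh.faces)
        frame2 = ep.compute_vertex_frame(moved)
        np.testing.assert_allclose(frame2.areas, frame.areas, rtol=1e-9, atol=1e-12)
        assert np.max(np.linalg.norm(frame2.normals - frame.normals @ R.T, axis=1)) < 1e-9


class TestNeighbors:
    def _point_mesh(self, pts):
        return ep.SurfaceMesh(np.asarray(pts, dtype=float), np.zeros((0, 3), dtype=int))

    def test_two_points_within(self):
        pairs = ep.neighbors_within(self._point_mesh([[0, 0, 0], [4, 0, 0]]), l0=5.0)
        assert pairs.n_pairs == 2  # symmetric: (0,1) and (1,0)
        np.testing.assert_allclose(pairs.r, [4.0, 4.0])

    def test_boundary_distance_excluded(self):
        pairs = ep.neighbors_within(self._point_mesh([[0, 0, 0], [5, 0, 0]]), l0=5.0)
        assert pairs.n_pairs == 0  # strict gate: r == l0 drops out

    def test_matches_brute_force_on_random_cloud(self, rng):
        pts = rng.uniform(0, 10, size=(200, 3))
        pairs = ep.neighbors_within(self._point_mesh(pts), l0=3.0)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        ii, jj = np.nonzero((d > 1e-6) & (d < 3.0))
        expected = set(zip(ii.tolist(), jj.tolist()))
        got = set(zip(pairs.i.tolist(), pairs.j.tolist()))
        assert got == expected

    def test_symmetry(self, sulcus25):
        mesh, _, _ = sulcus25
        pairs = ep.neighbors_within(mesh, l0=3.0)
        got = set(zip(pairs.i.tolist(), pairs.j.tolist()))
        assert all((j, i) in got for i, j in got)
        assert np.all(pairs.r > 0) and np.all(pairs.r < 3.0)


class TestGeodesics:
    @staticmethod
    def _strip(n):
        """Triangulated strip along x with unit quads."""
        top = np.column_stack([np.arange(n + 1), np.ones(n + 1), np.zeros(n + 1)])
        bot = np.column_stack([np.arange(n + 1), np.zeros(n + 1), np.zeros(n + 1)])
        v = np.vstack([bot, top])
        f = []
        for i in range(n):
            f += [[i, i + 1, n + 1 + i + 1], [i, n + 1 + i + 1, n + 1 + i]]
        return ep.SurfaceMesh(v, np.array(f))

    def test_unit_edge_chain(self):
        mesh = self._strip(10)
        d = ep.geodesic_distances(mesh, source=0)
        np.testing.assert_allclose(d[:11], np.arange(11.0))

    def test_geodesic_at_least_euclidean(self, sulcus25):
        mesh, _, _ = sulcus25
        d = ep.geodesic_distances(mesh, source=0)
        eu = np.linalg.norm(mesh.vertices - mesh.vertices[0], axis=1)
        assert np.all(d >= eu - 1e-9)

    def test_planar_limit_along_lattice_directions(self):
        """On a fine flat grid the edge-graph distance is exact along the
        axis and triangulated-diagonal directions (within 5%)."""
        mesh = ep.make_flat_sheet(side=10.0, spacing=0.5)
        center = int(np.argmin(np.linalg.norm(mesh.vertices, axis=1)))
        d = ep.geodesic_distances(mesh, source=center)
        eu = np.linalg.norm(mesh.vertices - mesh.vertices[center], axis=1)
        rel = mesh.vertices - mesh.vertices[center]
        axis = (np.abs(rel[:, 0]) < 1e-9) | (np.abs(rel[:, 1]) < 1e-9)
        diag = np.abs(rel[:, 0] - rel[:, 1]) < 1e-9
        sel = (axis | diag) & (eu > 1e-9)
        assert np.max(d[sel] / eu[sel]) < 1.05

    def test_max_dist_truncates(self, sulcus25):
        mesh, _, _ = sulcus25
        d = ep.geodesic_distances(mesh, source=0, max_dist=3.0)
        assert np.isinf(d).any() and np.all(d[np.isfinite(d)] <= 3.0)

    def test_source_out_of_range(self, flat_sheet):
        mesh, _ = flat_sheet
        with pytest.raises(IndexError):
            ep.geodesic_distances(mesh, source=mesh.n_vertices)
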