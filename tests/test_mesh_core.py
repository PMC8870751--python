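"""Mesh container, STL round trips and geometric primitives."""

import numpy as np
import pytest
import trimesh

from kneemorph import mesh_core as mc


# ---------------------------------------------------------------------------
# STL IO
# ---------------------------------------------------------------------------

class TestStlIO:
    def test_unit_cube_welds_to_8_vertices(self, unit_cube, tmp_path):
        path = tmp_path / "cube.stl"
        mc.write_stl(unit_cube, path)
        back = mc.read_stl(path)
        assert len(back.vertices) == 8
        assert len(back.faces) == 12

    def test_roundtrip_preserves_areas(self, plain_cap, tmp_path):
        path = tmp_path / "shell.stl"
        mc.write_stl(plain_cap.closed_shell, path)
        back = mc.read_stl(path)
        assert len(back.faces) == len(plain_cap.closed_shell.faces)
        np.testing.assert_allclose(
            mc.surface_area(back), mc.surface_area(plain_cap.closed_shell),
            rtol=1e-4,
        )

    def test_ascii_and_binary_encodings_agree(self, unit_cube, tmp_path):
        mesh = unit_cube.to_trimesh()
        p_bin, p_asc = tmp_path / "b.stl", tmp_path / "a.stl"
        mesh.export(p_bin, file_type="stl")
        mesh.export(p_asc, file_type="stl_ascii")
        a, b = mc.read_stl(p_asc), mc.read_stl(p_bin)
        assert len(a.faces) == len(b.faces)
        np.testing.assert_allclose(
            sorted(a.face_areas), sorted(b.face_areas), atol=1e-6
        )

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            mc.read_stl(tmp_path / "nope.stl")


# ---------------------------------------------------------------------------
# areas and volumes
# ---------------------------------------------------------------------------

class TestAreaVolume:
    def test_unit_cube(self, unit_cube):
        assert mc.surface_area(unit_cube) == pytest.approx(6.0)
        assert mc.enclosed_volume(unit_cube) == pytest.approx(1.0)

    def test_icosphere_analytic(self, icosphere_r10):
        assert mc.surface_area(icosphere_r10) == pytest.approx(
            4 * np.pi * 100, rel=0.01
        )
        assert mc.enclosed_volume(icosphere_r10) == pytest.approx(
            (4 / 3) * np.pi * 1000, rel=0.01
        )

    def test_reversed_orientation_rejected(self, unit_cube):
        flipped = mc.TriSurface(unit_cube.vertices, unit_cube.faces[:, ::-1])
        with pytest.raises(mc.MeshValidationError, match="inward"):
            mc.enclosed_volume(flipped)

    def test_open_surface_has_no_volume(self, holed_cap):
        with pytest.raises(mc.MeshValidationError):
            mc.enclosed_volume(holed_cap.outer_patch)

    def test_volume_translation_invariant(self, icosphere_coarse):
        moved = mc.TriSurface(
            icosphere_coarse.vertices + np.array([5.0, -3.0, 11.0]),
            icosphere_coarse.faces,
        )
        np.testing.assert_allclose(
            mc.enclosed_volume(moved), mc.enclosed_volume(icosphere_coarse),
            rtol=1e-9,
        )

    def test_area_rotation_invariant(self, icosphere_coarse):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        turned = mc.TriSurface(
            icosphere_coarse.vertices @ rot.T, icosphere_coarse.faces
        )
        np.testing.assert_allclose(
            mc.surface_area(turned), mc.surface_area(icosphere_coarse),
            rtol=1e-9,
        )


# ---------------------------------------------------------------------------
# boundary loops
# ---------------------------------------------------------------------------

class TestBoundaryLoops:
    def test_closed_shell_has_no_loops(self, plain_cap):
        assert mc.boundary_loops(plain_cap.closed_shell) == []

    def test_open_cap_is_a_disk(self, plain_cap):
        loops = mc.boundary_loops(plain_cap.outer_patch)
        assert len(loops) == 1
        assert loops[0].classification == "outer"

    def test_three_punched_holes_give_four_loops(self, holed_cap):
        loops = mc.boundary_loops(holed_cap.outer_patch)
        assert len(loops) == 4
        kinds = sorted(l.classification for l in loops)
        assert kinds == ["interior", "interior", "interior", "outer"]

    def test_edge_count_conservation(self, holed_cap):
        surface = holed_cap.outer_patch
        loops = mc.boundary_loops(surface)
        assert sum(l.n_vertices for l in loops) == len(surface.boundary_edges)

    def test_nonmanifold_edge_rejected(self):
        # three triangles sharing one edge
        verts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (0, -1, 0)]
        faces = [(0, 1, 2), (0, 1, 3), (0, 1, 4)]
        surf = mc.TriSurface(np.array(verts, float), np.array(faces))
        with pytest.raises(mc.MeshValidationError, match="non-manifold"):
            mc.boundary_loops(surf)


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def _brute_force_hits(surface, origins, directions, eps=1e-6):
    """Independent oracle: per-triangle loop, vectorized over rays.

    Plane intersection + inside test via signed tetrahedron volumes —
    a different formulation from the implementation's Moller-Trumbore.
    """
    n_rays = len(origins)
    best_t = np.full(n_rays, np.inf)
    best_f = np.full(n_rays, -1)
    for fi, tri in enumerate(surface.triangles):
        v0, v1, v2 = tri
        normal = np.cross(v1 - v0, v2 - v0)
        denom = directions @ normal
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((v0 - origins) @ normal) / denom
        ok = (np.abs(denom) > 1e-12) & (t > eps)
        pts = origins + t[:, None] * directions
        # barycentric inside test
        for a, b in ((v0, v1), (v1, v2), (v2, v0)):
            edge_n = np.cross(b - a, normal)
            ok &= ((pts - a) @ edge_n) <= 1e-9 * np.linalg.norm(edge_n)
        better = ok & (t < best_t)
        best_t[better] = t[better]
        best_f[better] = fi
    return best_f, best_t


class TestRayCasting:
    def test_parallel_plates(self):
        verts = np.array([
            (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
            (0, 0, 2), (1, 0, 2), (1, 1, 2), (0, 1, 2),
        ], float)
        faces = np.array([(0, 1, 2), (0, 2, 3), (4, 5, 6), (4, 6, 7)])
        surf = mc.TriSurface(verts, faces)
        hit = mc.ray_first_hit(surf, (0.4, 0.4, 0.0), (0, 0, 1),
                               excluded_faces=[0, 1])
        assert hit is not None
        assert hit[1] == pytest.approx(2.0)
        # parallel ray misses everything
        assert mc.ray_first_hit(surf, (0.4, 0.4, 1.0), (1, 0, 0)) is None

    def test_zero_direction_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            mc.ray_first_hit(unit_cube, (0, 0, 0), (0, 0, 0))

    def test_1000_random_rays_match_brute_force(self, icosphere_coarse, rng):
        n = 1000
        origins = rng.normal(0, 3, size=(n, 3))
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        oracle_f, oracle_t = _brute_force_hits(
            icosphere_coarse, origins, directions
        )
        for i in range(n):
            hit = mc.ray_first_hit(icosphere_coarse, origins[i], directions[i])
            if oracle_f[i] < 0:
                assert hit is None
            else:
                assert hit is not None
                assert hit[0] == oracle_f[i]
                assert hit[1] == pytest.approx(oracle_t[i], abs=1e-9)


# ---------------------------------------------------------------------------
# container validation
# ---------------------------------------------------------------------------

class TestTriSurface:
    def test_degenerate_faces_dropped(self):
        verts = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0.5, 0, 0)], float)
        faces = np.array([(0, 1, 2), (0, 1, 3)])  # second face collinear
        surf = mc.TriSurface(verts, faces)
        assert len(surf.faces) == 1

    def test_out_of_range_indices_rejected(self):
        with pytest.raises(mc.MeshValidationError):
            mc.TriSurface(np.zeros((3, 3)), np.array([[0, 1, 7]]))

    def test_validation_report_fields(self, holed_cap):
        rep = holed_cap.outer_patch.validation_report()
        assert rep["closed"] is False
        assert rep["n_boundary_loops"] == 4
        assert rep["n_nonmanifold_edges"] == 0
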