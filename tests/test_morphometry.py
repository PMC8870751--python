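"""Wall thickness, discrete Gaussian curvature, hole detection and grading."""

import numpy as np
import pytest

from kneemorph import mesh_core as mc
from kneemorph import morphometry as mm
from kneemorph.synthetic_knee import EllipseHole, generate_shell


# ---------------------------------------------------------------------------
# wall thickness
# ---------------------------------------------------------------------------

class TestWallThickness:
    def test_uniform_sphere_shell(self, sphere_shell):
        field = mm.wall_thickness(sphere_shell)
        vals = field.values[field.valid]
        frac = np.mean((vals >= 1.9) & (vals <= 2.1))
        assert frac >= 0.99

    def test_slab_interior_faces_exact(self, slab_3p5):
        field = mm.wall_thickness(slab_3p5)
        surf = slab_3p5
        # top/bottom faces away from the side walls
        interior = (
            (np.abs(np.abs(surf.face_normals[:, 2]) - 1.0) < 1e-9)
            & (surf.face_centroids[:, 0] > 3.0)
            & (surf.face_centroids[:, 0] < 17.0)
            & (surf.face_centroids[:, 1] > 3.0)
            & (surf.face_centroids[:, 1] < 17.0)
        )
        assert interior.sum() > 50
        np.testing.assert_allclose(field.values[interior], 3.5, atol=1e-6)

    def test_thinning_patch_recovers_ground_truth(self, patched_cap):
        field = mm.wall_thickness(patched_cap.closed_shell)
        n_outer = len(patched_cap.outer_patch.faces)
        vals = field.values[:n_outer]
        valid = field.valid[:n_outer]
        thinned = (patched_cap.face_class == 1) & valid
        plain = (patched_cap.face_class == 0) & valid
        assert thinned.sum() > 30
        assert np.median(vals[thinned]) == pytest.approx(1.0, abs=0.05)
        assert np.median(vals[plain]) == pytest.approx(2.0, abs=0.05)
        # histogram mass near the thin mode matches the analytic patch fraction
        near_thin = np.mean(np.abs(vals[valid] - 1.0) < 0.3)
        assert near_thin == pytest.approx(
            patched_cap.patch_area_fraction, abs=0.06
        )

    def test_open_surface_rejected(self, plain_cap):
        with pytest.raises(mc.MeshValidationError, match="closed"):
            mm.wall_thickness(plain_cap.outer_patch)

    def test_rigid_motion_and_scaling(self, sphere_shell):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [0.5, 1.0, -0.7]).as_matrix()
        moved = mc.TriSurface(
            sphere_shell.vertices @ rot.T + np.array([3.0, 4.0, 5.0]),
            sphere_shell.faces,
        )
        base = mm.wall_thickness(sphere_shell)
        after = mm.wall_thickness(moved)
        np.testing.assert_allclose(
            after.values[after.valid], base.values[base.valid], atol=1e-6
        )
        scaled = mc.TriSurface(sphere_shell.vertices * 2.0, sphere_shell.faces)
        twice = mm.wall_thickness(scaled)
        np.testing.assert_allclose(
            twice.values[twice.valid], 2.0 * base.values[base.valid], atol=1e-6
        )


# ---------------------------------------------------------------------------
# Gaussian curvature
# ---------------------------------------------------------------------------

class TestGaussianCurvature:
    def test_icosphere_matches_1_over_r2(self, icosphere_r10):
        field = mm.gaussian_curvature(icosphere_r10)
        assert field.valid.all()
        np.testing.assert_allclose(field.values, 0.01, rtol=0.05)

    def test_planar_grid_interior_is_flat(self, slab_3p5):
        field = mm.gaussian_curvature(slab_3p5)
        surf = slab_3p5
        interior = (
            (np.abs(surf.face_normals[:, 2] - 1.0) < 1e-9)
            & (surf.face_centroids[:, 0] > 3.0)
            & (surf.face_centroids[:, 0] < 17.0)
            & (surf.face_centroids[:, 1] > 3.0)
            & (surf.face_centroids[:, 1] < 17.0)
        )
        np.testing.assert_allclose(field.values[interior], 0.0, atol=1e-9)

    def test_boundary_vertices_flagged_invalid(self, plain_cap):
        # a lone triangle has only boundary vertices: no curvature defined
        tri = mc.TriSurface(
            np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0)], float),
            np.array([(0, 1, 2)]),
        )
        lone = mm.gaussian_curvature(tri)
        assert not lone.valid.any()
        # on an open cap, faces keep a value via their interior vertices
        field = mm.gaussian_curvature(plain_cap.outer_patch)
        assert field.valid.mean() > 0.95

    @pytest.mark.parametrize("fixture_name,chi", [
        ("sphere_shell", 4),       # two disjoint closed components
        ("plain_cap", 2),          # genus 0
        ("holed_cap", -4),         # genus 3: chi = 2 - 2*3
        ("slab_3p5", 2),
    ])
    def test_gauss_bonnet(self, fixture_name, chi, request):
        obj = request.getfixturevalue(fixture_name)
        surf = getattr(obj, "closed_shell", obj)
        assert surf.euler_characteristic == chi
        deficit = mm.total_angle_deficit(surf)
        assert deficit == pytest.approx(2 * np.pi * chi, rel=1e-8)


# ---------------------------------------------------------------------------
# hole detection and ellipse fitting
# ---------------------------------------------------------------------------

class TestDetectHoles:
    def test_circular_hole_radius_3(self):
        comp = generate_shell(
            40.0, 2.0, holes=[EllipseHole((4.0, 2.0), 3.0, 3.0)],
            refinement=2, seed=5,
        )
        records = mm.detect_holes(comp.outer_patch, "fem_cart")
        assert len(records) == 1
        rec = records[0]
        assert rec.semi_axis_a == pytest.approx(3.0, rel=0.05)
        assert rec.semi_axis_b == pytest.approx(3.0, rel=0.05)
        assert rec.area_mm2 == pytest.approx(np.pi * 9, rel=0.05)

    def test_elliptical_hole_4_by_2(self):
        comp = generate_shell(
            40.0, 2.0, holes=[EllipseHole((-6.0, 5.0), 4.0, 2.0, angle=1.1)],
            refinement=2, seed=6,
        )
        records = mm.detect_holes(comp.outer_patch, "fem_cart")
        assert len(records) == 1
        assert records[0].area_mm2 == pytest.approx(np.pi * 8, rel=0.05)

    def test_no_interior_loops_gives_empty_list(self, plain_cap):
        assert mm.detect_holes(plain_cap.outer_patch) == []

    def test_closed_input_gives_empty_list(self, plain_cap):
        assert mm.detect_holes(plain_cap.closed_shell) == []

    @pytest.mark.parametrize("n_holes", [0, 1, 2, 3, 4, 5])
    def test_hole_count_recovery(self, n_holes):
        rng = np.random.default_rng(40 + n_holes)
        holes, centers = [], []
        radius_ring = 16.0
        for k in range(n_holes):
            ang = 2 * np.pi * k / max(n_holes, 1)
            c = (radius_ring * np.cos(ang), radius_ring * np.sin(ang))
            a = float(rng.uniform(1.5, 3.0))
            holes.append(EllipseHole(c, a, a * rng.uniform(0.6, 1.0)))
        comp = generate_shell(40.0, 2.0, holes=holes, refinement=2,
                              seed=100 + n_holes)
        records = mm.detect_holes(comp.outer_patch)
        assert len(records) == n_holes
        got = sorted(r.area_mm2 for r in records)
        want = sorted(comp.true_hole_areas)
        np.testing.assert_allclose(got, want, rtol=0.10)

    def test_euler_characteristic_counts_holes(self):
        for g, fixture_seed in ((1, 21), (2, 22)):
            holes = [
                EllipseHole((12.0 * (-1) ** k, 8.0 * k - 4.0), 2.5, 2.0)
                for k in range(g)
            ]
            comp = generate_shell(40.0, 2.0, holes=holes, refinement=2,
                                  seed=fixture_seed)
            assert comp.closed_shell.euler_characteristic == 2 - 2 * g


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

class TestGrading:
    def _rec(self, area):
        a = np.sqrt(area / np.pi)
        loop = None
        return mm.HoleRecord("fem_cart", loop, a, a)

    def test_no_holes_grade_zero(self):
        assert mm.grade_compartment([]) == (0, 0.0, 0)

    def test_small_total_grade_one(self):
        grade, total, n = mm.grade_compartment([self._rec(1.18)])
        assert grade == 1
        assert total == pytest.approx(1.18)

    def test_large_total_grade_two(self):
        grade, total, n = mm.grade_compartment([self._rec(186.83)])
        assert grade == 2
        assert total == pytest.approx(186.83)

    def test_boundary_inclusive(self):
        # a = b = 2.523 mm realizes the boundary area (pi*a*b = 19.998 <= 20)
        rec = mm.HoleRecord("fem_cart", None, 2.523, 2.523)
        grade, total, _ = mm.grade_compartment([rec])
        assert total == pytest.approx(20.0, abs=0.005)
        assert grade == 1
        assert mm.grade_from_area(20.0, 1) == 1  # inclusive cutoff
        grade2, _, _ = mm.grade_compartment([self._rec(20.01)])
        assert grade2 == 2

    def test_grade_from_area_table(self):
        assert mm.grade_from_area(186.83, 2) == 2
        assert mm.grade_from_area(1.18, 1) == 1
        assert mm.grade_from_area(0.0, 0) == 0


# ---------------------------------------------------------------------------
# field files
# ---------------------------------------------------------------------------

class TestFieldFiles:
    def test_roundtrip(self, patched_cap, tmp_path):
        field = mm.gaussian_curvature(patched_cap.outer_patch)
        path = tmp_path / "curv.txt"
        mm.write_field_file(field, path)
        back = mm.read_field_file(path, "curvature")
        assert back.n_valid == field.n_valid
        np.testing.assert_allclose(
            np.sort(back.values), np.sort(field.values[field.valid]), rtol=1e-6
        )

    def test_nine_numbers_is_an_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0 0 1 0 0 0 1 0 2.0\n0 0 0 1 0 0 0 1 0\n")
        with pytest.raises(ValueError, match="bad.txt:2"):
            mm.read_field_file(path)

    def test_line_count_equals_element_count(self, tmp_path):
        lines = []
        for i in range(7):
            z = float(i)
            lines.append(f"0 0 {z} 1 0 {z} 0 1 {z} {1.5 + i}")
        path = tmp_path / "field.txt"
        path.write_text("\n".join(lines) + "\n")
        field = mm.read_field_file(path)
        assert field.n_valid == 7
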