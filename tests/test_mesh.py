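"""Mesh model, planimetry and standard-format round-trips."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundmetry import (
    TriangleMesh,
    face_areas,
    read_mesh,
    submesh,
    surface_area,
    validate_mesh,
    write_mesh,
)
from woundmetry.exceptions import (
    EmptyMeshError,
    EmptySelectionError,
    MeshReadError,
    UnsupportedFormatError,
)


class TestFaceAreas:
    def test_right_triangle_half_mm2(self):
        m = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        assert face_areas(m) == pytest.approx([0.5])

    def test_equilateral_side_2mm(self):
        m = TriangleMesh(
            [[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]], [[0, 1, 2]]
        )
        assert face_areas(m) == pytest.approx([math.sqrt(3)])

    def test_orientation_independent_nonnegative(self, square_mesh):
        flipped = TriangleMesh(square_mesh.vertices, square_mesh.faces[:, ::-1])
        assert (face_areas(flipped) >= 0).all()
        assert face_areas(flipped) == pytest.approx(face_areas(square_mesh))


class TestSurfaceArea:
    def test_unit_square_is_0_01_cm2(self, square_mesh):
        assert surface_area(square_mesh) == pytest.approx(0.01)

    def test_cm2_conversion_matches_mm2_sum_exactly(self, painted_cylinder):
        mesh, _ = painted_cylinder
        assert surface_area(mesh) * 100.0 == float(face_areas(mesh).sum())

    def test_additive_over_disjoint_subsets(self, painted_cylinder):
        mesh, _ = painted_cylinder
        rng = np.random.default_rng(7)
        faces = rng.permutation(mesh.n_faces)
        a, b = faces[: mesh.n_faces // 3], faces[mesh.n_faces // 3:]
        total = surface_area(mesh, a) + surface_area(mesh, b)
        assert total == pytest.approx(surface_area(mesh), rel=1e-9)

    def test_empty_subset_warns_and_returns_zero(self, square_mesh):
        with pytest.warns(UserWarning, match="empty"):
            assert surface_area(square_mesh, []) == 0.0

    def test_closed_cylinder_lateral_area(self, painted_cylinder, cylinder_scene):
        mesh, _ = painted_cylinder
        p = cylinder_scene.anatomy_params
        lateral = 2 * math.pi * p["radius"] * p["length"] / 100.0
        assert surface_area(mesh) == pytest.approx(lateral, rel=0.005)

    def test_spherical_cap_closed_form(self, painted_cap, cap_scene):
        mesh, truth = painted_cap
        r = cap_scene.anatomy_params["radius"]
        analytic = 2 * math.pi * r * r * (1 - math.cos(0.3)) / 100.0
        assert truth == pytest.approx(analytic)
        faces = np.nonzero((mesh.vertex_labels[mesh.faces] == 1).all(axis=1))[0]
        assert surface_area(mesh, faces) == pytest.approx(analytic, rel=0.005)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angles=st.tuples(*[st.floats(-math.pi, math.pi) for _ in range(3)]),
        shift=st.tuples(*[st.floats(-100, 100) for _ in range(3)]),
    )
    def test_rigid_motion_invariance(self, angles, shift):
        from scipy.spatial.transform import Rotation

        mesh = TriangleMesh(
            [[0, 0, 0], [3, 0, 0], [3, 2, 0], [0, 2, 0], [1, 1, 2]],
            [[0, 1, 2], [0, 2, 3], [0, 1, 4], [1, 2, 4]],
        )
        rot = Rotation.from_euler("xyz", angles).as_matrix()
        moved = TriangleMesh(mesh.vertices @ rot.T + np.asarray(shift), mesh.faces)
        assert surface_area(moved) == pytest.approx(surface_area(mesh), rel=1e-9)


class TestValidateMesh:
    def test_clean_mesh_unchanged(self, square_mesh):
        out = validate_mesh(square_mesh)
        assert out.n_faces == 2
        assert out.n_vertices == 4

    def test_removes_collapsed_face_and_keeps_rest(self):
        rng = np.random.default_rng(0)
        verts = rng.uniform(0, 10, (300, 3))
        faces = rng.integers(0, 300, (99, 3))
        # ensure the 99 random faces are non-degenerate
        faces = faces[
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        ]
        collapsed = np.array([[5, 5, 9]])
        m = TriangleMesh(verts, np.concatenate([faces, collapsed]))
        assert validate_mesh(m).n_faces == len(faces)

    def test_zero_area_but_distinct_vertices_removed(self):
        m = TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]],
                         [[0, 1, 2], [0, 1, 3]])
        assert validate_mesh(m).n_faces == 1

    def test_all_faces_degenerate_raises(self):
        m = TriangleMesh([[0, 0, 0], [1, 0, 0]], [[0, 0, 1]])
        with pytest.raises(EmptyMeshError):
            validate_mesh(m)

    def test_drops_unreferenced_vertices_and_reindexes_channels(self):
        m = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [9, 9, 9]],
            [[0, 1, 2]],
            vertex_colors=np.tile([0.5, 0.5, 0.5], (4, 1)),
            vertex_labels=[1, 1, 1, 7],
        )
        out = validate_mesh(m)
        assert out.n_vertices == 3
        assert list(out.vertex_labels) == [1, 1, 1]
        assert out.vertex_colors.shape == (3, 3)

    def test_jittered_limb_area_within_1pct(self, cylinder_scene):
        from woundmetry import apply_scan_noise, make_anatomy

        mesh = make_anatomy(cylinder_scene)
        noisy = apply_scan_noise(mesh, 0.05, seed=3)
        cleaned = validate_mesh(noisy)
        assert cleaned.n_faces == mesh.n_faces
        assert surface_area(cleaned) == pytest.approx(surface_area(mesh), rel=0.01)


class TestSubmesh:
    def test_full_face_set_identity_up_to_reindexing(self, square_mesh):
        out = submesh(square_mesh, range(square_mesh.n_faces))
        assert out.n_faces == square_mesh.n_faces
        assert surface_area(out) == pytest.approx(surface_area(square_mesh))

    def test_single_face(self, square_mesh):
        out = submesh(square_mesh, [1])
        assert (out.n_vertices, out.n_faces) == (3, 1)

    def test_empty_set_raises(self, square_mesh):
        with pytest.raises(EmptySelectionError):
            submesh(square_mesh, [])

    def test_area_matches_subset_area(self, painted_cap):
        mesh, _ = painted_cap
        faces = np.nonzero((mesh.vertex_labels[mesh.faces] == 1).all(axis=1))[0]
        assert surface_area(submesh(mesh, faces)) == pytest.approx(
            surface_area(mesh, faces), rel=1e-12
        )


class TestMeshIO:
    def test_ply_roundtrip_identity(self, tmp_path, colored_square):
        p = tmp_path / "sq.ply"
        write_mesh(p, colored_square)
        back = read_mesh(p)
        assert (back.n_vertices, back.n_faces) == (4, 2)
        assert back.vertex_colors == pytest.approx(colored_square.vertex_colors, abs=1 / 255)

    @pytest.mark.parametrize("fmt", ["ply", "obj", "stl"])
    def test_roundtrip_preserves_area_to_6_digits(self, tmp_path, fmt, painted_cylinder):
        mesh, _ = painted_cylinder
        p = tmp_path / f"limb.{fmt}"
        write_mesh(p, mesh)
        back = read_mesh(p)
        assert surface_area(back) == pytest.approx(surface_area(mesh), rel=1e-6)

    def test_stl_has_no_colors(self, tmp_path, colored_square):
        p = tmp_path / "sq.stl"
        write_mesh(p, colored_square)
        assert read_mesh(p).vertex_colors is None

    def test_labels_sidecar_roundtrip(self, tmp_path, colored_square):
        p = tmp_path / "sq.ply"
        side = tmp_path / "sq.labels.csv"
        write_mesh(p, colored_square, labels_path=side)
        back = read_mesh(p, labels_path=side)
        assert list(back.vertex_labels) == list(colored_square.vertex_labels)

    def test_ascii_stl_with_degenerate_triangle_loads_then_cleans(self, tmp_path):
        stl = "\n".join([
            "solid junk",
            " facet normal 0 0 1",
            "  outer loop",
            "   vertex 0 0 0", "   vertex 1 0 0", "   vertex 2 0 0",
            "  endloop", " endfacet",
            " facet normal 0 0 1",
            "  outer loop",
            "   vertex 0 0 0", "   vertex 1 0 0", "   vertex 0 1 0",
            "  endloop", " endfacet",
            "endsolid junk",
        ])
        p = tmp_path / "deg.stl"
        p.write_text(stl)
        mesh = read_mesh(p)
        assert mesh.n_faces == 2
        assert validate_mesh(mesh).n_faces == 1

    def test_missing_file_error_names_path(self, tmp_path):
        with pytest.raises(MeshReadError, match="nowhere.ply"):
            read_mesh(tmp_path / "nowhere.ply")

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(UnsupportedFormatError):
            read_mesh(tmp_path / "scan.vtk")


class TestInvariants:
    def test_partition_additivity(self, painted_cap):
        mesh, _ = painted_cap
        rng = np.random.default_rng(11)
        assignment = rng.integers(0, 4, mesh.n_faces)
        parts = [np.nonzero(assignment == k)[0] for k in range(4)]
        assert sum(surface_area(mesh, p) for p in parts) == pytest.approx(
            surface_area(mesh), rel=1e-9
        )

    def test_face_index_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 3]])

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]],
                         vertex_labels=[1, 0])
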