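"""Mesh volumetrics, path lengths, insertion angles and lever arms."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dryskull.geometry import (
    AnatomicalFrame,
    MeshError,
    MuscleGeometry,
    TriMesh,
    insertion_angles,
    lever_lengths,
    mesh_volume,
    path_length,
)
from conftest import make_cube


class TestMeshVolume:
    def test_unit_cube(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_orientation_normalised(self, unit_cube):
        flipped = TriMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        assert mesh_volume(flipped) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_converges_to_analytic_volume(self):
        r = 10.0
        exact = 4.0 / 3.0 * np.pi * r**3
        errs = []
        for sub in (2, 3, 4):
            ico = trimesh.creation.icosphere(subdivisions=sub, radius=r)
            m = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
            errs.append(abs(mesh_volume(m) - exact) / exact)
        assert errs[-1] < 0.01  # 4188.79 mm^3 within 1%
        assert errs[0] > errs[1] > errs[2]  # converging

    def test_agrees_with_independent_mesh_library(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=7.3)
        ours = mesh_volume(TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces)))
        assert ours == pytest.approx(float(ico.volume), rel=1e-12)

    def test_open_mesh_rejected_with_edges_named(self, unit_cube):
        open_mesh = TriMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(MeshError, match="not closed"):
            mesh_volume(open_mesh)

    def test_rigid_motion_invariance(self, unit_cube):
        rng = np.random.default_rng(42)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = TriMesh(unit_cube.vertices @ rot.T + rng.uniform(-100, 100, 3), unit_cube.faces)
        assert mesh_volume(moved) == pytest.approx(1.0, rel=1e-9)

    def test_disjoint_union_adds_volumes(self):
        v1, f1 = make_cube(origin=(0, 0, 0), side=1.0)
        v2, f2 = make_cube(origin=(5, 5, 5), side=2.0)
        mesh = TriMesh(np.vstack([v1, v2]), np.vstack([f1, f2 + len(v1)]))
        assert mesh_volume(mesh) == pytest.approx(1.0 + 8.0, rel=1e-12)


class TestPathLength:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(0, 0, 0), (0, 0, 43.4)], 43.4),
            ([(0, 0, 0), (3, 0, 0), (3, 4, 0)], 7.0),
        ],
    )
    def test_known_polylines(self, points, expected):
        assert path_length(points) == pytest.approx(expected, abs=1e-12)

    def test_matches_per_segment_summation(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-50, 50, size=(10, 3))
        brute = sum(
            float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(len(pts) - 1)
        )
        assert path_length(pts) == pytest.approx(brute, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 2"):
            path_length([(0, 0, 0)])


class TestInsertionAngles:
    frame = AnatomicalFrame.standard()

    def test_vertical_line_of_action(self):
        assert insertion_angles((0, 0, 10), (0, 0, 0), self.frame) == (0.0, 0.0)

    def test_45_degrees_in_sagittal_plane(self):
        alpha, beta = insertion_angles((10, 0, 10), (0, 0, 0), self.frame)
        assert alpha == pytest.approx(45.0, abs=1e-12)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_against_projection_oracle(self):
        # oracle: project the line of action onto the plane explicitly, then
        # arccos of the normalised dot with the vertical axis, folded to <90
        rng = np.random.default_rng(11)
        for _ in range(100):
            o, i = rng.uniform(-30, 30, 3), rng.uniform(-30, 30, 3)
            if np.allclose(o, i):
                continue
            v = o - i

            def oracle(normal):
                p = v - np.dot(v, normal) * normal
                n = np.linalg.norm(p)
                if n == 0:
                    return 0.0
                return np.degrees(np.arccos(np.clip(abs(p[2]) / n, -1, 1)))

            alpha, beta = insertion_angles(o, i, self.frame)
            assert alpha == pytest.approx(oracle(np.array([0.0, 1, 0])), abs=1e-9)
            assert beta == pytest.approx(oracle(np.array([1.0, 0, 0])), abs=1e-9)

    def test_degenerate_projection_defined_zero(self):
        alpha, beta = insertion_angles((0, 5, 0), (0, 0, 0), self.frame)
        assert alpha == 0.0  # purely mediolateral: no sagittal projection
        assert beta == pytest.approx(90.0, abs=1e-9)  # horizontal: cannot adduct

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(derandomize=True, max_examples=25)
    def test_invariant_under_uniform_scaling(self, scale):
        o, i = np.array([7.0, 3.0, 19.0]), np.array([1.0, -2.0, 4.0])
        base = insertion_angles(o, i, self.frame)
        scaled = insertion_angles(o * scale, i * scale, self.frame)
        assert scaled == pytest.approx(base, abs=1e-9)


class TestLevers:
    def test_collinear_configuration(self):
        inl, outs = lever_lengths((0, 0, 0), (19.8, 0, 0), [(90.4, 0, 0)])
        assert inl == pytest.approx(19.8)
        assert outs[0] == pytest.approx(90.4)

    def test_insertion_at_joint(self):
        inl, _ = lever_lengths((1, 2, 3), (1, 2, 3), [])
        assert inl == 0.0

    def test_random_matches_euclidean(self):
        rng = np.random.default_rng(5)
        j, ins = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
        bites = rng.uniform(-10, 10, (4, 3))
        inl, outs = lever_lengths(j, ins, bites)
        assert inl == pytest.approx(np.linalg.norm(ins - j), rel=1e-12)
        for o, b in zip(outs, bites):
            assert o == pytest.approx(np.linalg.norm(b - j), rel=1e-12)


class TestMuscleGeometry:
    @given(
        volume=st.floats(min_value=1.0, max_value=5e4),
        length=st.floats(min_value=1.0, max_value=100.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_csa_times_length_is_volume(self, volume, length):
        g = MuscleGeometry(volume, length)
        assert g.csa * g.length == pytest.approx(g.volume, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(volume=-1.0, length=10.0),
            dict(volume=1.0, length=0.0),
            dict(volume=1.0, length=10.0, alpha=90.0),
            dict(volume=1.0, length=10.0, beta=-1.0),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MuscleGeometry(**kwargs)


class TestAnatomicalFrame:
    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            AnatomicalFrame(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))

    def test_left_handed_rejected(self):
        with pytest.raises(ValueError, match="right-handed"):
            AnatomicalFrame(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, -1.0]))
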