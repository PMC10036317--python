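"""Geometry and measurement-chain unit tests."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from anthrobench.errors import (
    GeometryError,
    LandmarkError,
    TopologyError,
    UnitsError,
)
from anthrobench.mesh import (
    AnthropometricMesh,
    AnthropometryConstants,
    estimate_height,
    estimate_weight,
    foot_plane,
    is_watertight,
    load_mesh,
    measure,
    measure_ipd,
    mesh_volume,
    pupil_centers,
    scale_to_ipd,
)

from conftest import box_mesh, full_landmark_box, mesh_with_landmarks


class TestPupilsAndIPD:
    @pytest.mark.parametrize(
        "inner, outer, expected",
        [
            ((0, 0, 0), (2, 0, 0), (1, 0, 0)),
            ((1, 2, 3), (3, 4, 5), (2, 3, 4)),
            ((0.5, 0.5, 0.5), (0.5, 0.5, 0.5), (0.5, 0.5, 0.5)),  # coincident corners
        ],
    )
    def test_pupil_is_eye_corner_midpoint(self, inner, outer, expected):
        m = mesh_with_landmarks(
            {
                "left_eye_inner": inner,
                "left_eye_outer": outer,
                "right_eye_inner": (10, 0, 0),
                "right_eye_outer": (12, 0, 0),
            }
        )
        left, right = pupil_centers(m)
        assert np.allclose(left, expected)
        assert np.allclose(right, (11, 0, 0))

    @pytest.mark.parametrize(
        "lp, rp, expected",
        [
            ((0, 0, 0), (6.4, 0, 0), 6.4),
            ((0, 0, 0), (3, 4, 0), 5.0),  # 3-4-5 triangle
        ],
    )
    def test_ipd_is_pupil_distance(self, lp, rp, expected):
        m = mesh_with_landmarks(
            {
                "left_eye_inner": lp,
                "left_eye_outer": lp,
                "right_eye_inner": rp,
                "right_eye_outer": rp,
            }
        )
        assert measure_ipd(m) == pytest.approx(expected)

    def test_ipd_reflection_invariant(self):
        pts = {
            "left_eye_inner": (1, 2, 3),
            "left_eye_outer": (2, 2.5, 3),
            "right_eye_inner": (-1, 2, 3),
            "right_eye_outer": (-2, 2.5, 3),
        }
        m = mesh_with_landmarks(pts)
        mirrored = mesh_with_landmarks({k: (-v[0], v[1], v[2]) for k, v in pts.items()})
        assert measure_ipd(mirrored) == pytest.approx(measure_ipd(m))

    def test_missing_landmark_names_role(self):
        m = mesh_with_landmarks({"left_eye_inner": (0, 0, 0)})
        with pytest.raises(LandmarkError, match="left_eye_outer"):
            pupil_centers(m)


class TestScaling:
    def _raw_mesh_with_ipd(self, ipd):
        return mesh_with_landmarks(
            {
                "left_eye_inner": (ipd / 2, 0, 0),
                "left_eye_outer": (ipd / 2, 0, 0),
                "right_eye_inner": (-ipd / 2, 0, 0),
                "right_eye_outer": (-ipd / 2, 0, 0),
            },
            units="raw",
        )

    def test_scale_factor_male(self):
        scaled, s = scale_to_ipd(self._raw_mesh_with_ipd(2.0), "male")
        assert s == pytest.approx(3.20)
        assert scaled.units == "cm"

    def test_identity_when_already_at_mean(self):
        m = self._raw_mesh_with_ipd(6.17)
        scaled, s = scale_to_ipd(m, "female")
        assert s == pytest.approx(1.0)
        assert np.allclose(scaled.vertices, m.vertices)

    def test_post_scaling_ipd_equals_gender_mean(self):
        scaled, _ = scale_to_ipd(self._raw_mesh_with_ipd(2.7182), "male")
        assert measure_ipd(scaled) == pytest.approx(6.40, rel=1e-9)

    def test_unknown_gender_rejected(self):
        from anthrobench.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            scale_to_ipd(self._raw_mesh_with_ipd(2.0), "unknown")

    def test_zero_ipd_rejected(self):
        with pytest.raises(GeometryError):
            scale_to_ipd(self._raw_mesh_with_ipd(0.0), "male")

    def test_cm_mesh_rejected(self):
        m = self._raw_mesh_with_ipd(2.0)
        m.units = "cm"
        with pytest.raises(UnitsError):
            scale_to_ipd(m, "male")


class TestFootPlaneAndHeight:
    def test_canonical_plane(self):
        m = full_landmark_box()
        point, normal = foot_plane(m)
        assert np.allclose(normal, (0, 0, 1))

    def test_offset_plane_same_normal(self):
        m = mesh_with_landmarks(
            {
                "foot_a": (0, 0, 2),
                "foot_b": (1, 0, 2),
                "foot_c": (0, 1, 2),
                "head_apex": (0, 0, 50),
            }
        )
        point, normal = foot_plane(m)
        assert np.allclose(normal, (0, 0, 1))
        assert point[2] == pytest.approx(2.0)

    def test_collinear_feet_rejected(self):
        m = mesh_with_landmarks(
            {
                "foot_a": (0, 0, 0),
                "foot_b": (1, 0, 0),
                "foot_c": (2, 0, 0),
                "head_apex": (0, 0, 50),
            }
        )
        with pytest.raises(GeometryError, match="collinear"):
            foot_plane(m)

    def test_normal_points_toward_apex(self):
        # apex below the plane: normal must flip so distance stays positive
        m = mesh_with_landmarks(
            {
                "foot_a": (0, 0, 0),
                "foot_b": (1, 0, 0),
                "foot_c": (0, 1, 0),
                "head_apex": (0, 0, -170),
            },
            units="cm",
        )
        assert estimate_height(m) == pytest.approx(170.0)

    def test_axis_aligned_height(self):
        assert estimate_height(full_landmark_box(height=170.0)) == pytest.approx(170.0)

    def test_rigid_motion_invariance(self):
        m = full_landmark_box(height=170.0)
        h0 = estimate_height(m)
        rng = np.random.default_rng(11)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            moved = m.copy()
            moved.vertices = m.vertices @ rot.T + rng.normal(0, 50, 3)
            assert estimate_height(moved) == pytest.approx(h0, rel=1e-9)


def _orient(pts, hull):
    """Orient hull simplices outward using the outward facet normals."""
    faces = []
    for simplex, eq in zip(hull.simplices, hull.equations):
        a, b, c = pts[simplex]
        n = np.cross(b - a, c - a)
        faces.append(simplex if np.dot(n, eq[:3]) > 0 else simplex[[0, 2, 1]])
    return np.asarray(faces)


class TestVolume:
    def test_unit_cube(self):
        assert mesh_volume(box_mesh()) == pytest.approx(1.0)

    def test_translation_invariance(self):
        v1 = mesh_volume(box_mesh(size=2.5, offset=(100, -50, 3)))
        assert v1 == pytest.approx(2.5**3, rel=1e-12)

    def test_icosphere_converges_from_below(self):
        r = 2.0
        exact = 4 / 3 * np.pi * r**3
        vols = []
        for sub in range(1, 5):
            s = trimesh.creation.icosphere(subdivisions=sub, radius=r)
            vols.append(mesh_volume((np.asarray(s.vertices), np.asarray(s.faces))))
        assert all(v < exact for v in vols)  # inscribed polyhedra
        assert np.all(np.diff(vols) > 0)  # monotone refinement
        assert vols[-1] == pytest.approx(exact, rel=5e-3)

    def test_agrees_with_trimesh(self, male_mesh):
        tm = male_mesh.to_trimesh()
        assert mesh_volume(male_mesh) == pytest.approx(tm.volume, rel=1e-10)

    def test_convex_hull_monte_carlo_oracle(self):
        # point-sampling oracle, independent of the signed-tetrahedron sum
        rng = np.random.default_rng(42)
        pts = rng.normal(0, 1, (60, 3))
        hull = ConvexHull(pts)
        vol = mesh_volume((pts, _orient(pts, hull)))
        lo = pts.min(0) - 0.01
        hi = pts.max(0) + 0.01
        samples = rng.uniform(lo, hi, (400_000, 3))
        inside = np.all(
            samples @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-12, axis=1
        )
        mc = inside.mean() * np.prod(hi - lo)
        assert vol == pytest.approx(mc, rel=0.01)

    def test_non_watertight_reports_boundary_edges(self):
        verts, faces = box_mesh()
        with pytest.raises(TopologyError) as err:
            mesh_volume((verts, faces[:-1]))
        assert len(err.value.boundary_edges) == 3


class TestWeight:
    def test_known_volume_conversion(self):
        side = (0.07 * 1e6) ** (1 / 3)  # cube enclosing 0.07 m^3, in cm
        m = mesh_with_landmarks({}, units="cm", size=side)
        assert estimate_weight(m) == pytest.approx(71.61, rel=1e-9)

    def test_unit_cubic_metre(self):
        m = mesh_with_landmarks({}, units="cm", size=100.0)
        assert estimate_weight(m) == pytest.approx(1023.0)

    def test_inverted_orientation_rejected(self):
        verts, faces = box_mesh(size=10.0)
        m = AnthropometricMesh(verts, faces[:, [0, 2, 1]], {}, units="cm")
        with pytest.raises(GeometryError):
            estimate_weight(m)


class TestMeasureChain:
    def test_round_trip_male_template(self, male_mesh):
        bm = measure(male_mesh, "male")
        assert bm.height_cm == pytest.approx(176.1, rel=0.005)
        assert bm.weight_kg == pytest.approx(78.4, rel=0.005)
        assert bm.weight_kg == pytest.approx(bm.volume_m3 * 1023.0, rel=1e-12)

    def test_round_trip_female_template(self, female_mesh):
        bm = measure(female_mesh, "female")
        assert bm.height_cm == pytest.approx(161.1, rel=0.005)
        assert bm.weight_kg == pytest.approx(60.9, rel=0.005)

    def test_uniform_prescale_absorbed(self, male_mesh):
        bm0 = measure(male_mesh, "male")
        scaled = male_mesh.copy()
        scaled.vertices = scaled.vertices * 10.0
        bm1 = measure(scaled, "male")
        assert bm1.height_cm == pytest.approx(bm0.height_cm, rel=1e-9)
        assert bm1.weight_kg == pytest.approx(bm0.weight_kg, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
    def test_scale_equivariance_property(self, factor):
        m = full_landmark_box(height=170.0)
        m.units = "raw"
        bm0 = measure(m, "female")
        scaled = m.copy()
        scaled.vertices = scaled.vertices * factor
        bm1 = measure(scaled, "female")
        assert bm1.height_cm == pytest.approx(bm0.height_cm, rel=1e-9)
        assert bm1.weight_kg == pytest.approx(bm0.weight_kg, rel=1e-9)

    def test_gender_constant_ratio(self, male_mesh):
        f = measure(male_mesh, "female")
        m = measure(male_mesh, "male")
        ratio = 6.17 / 6.40
        assert f.height_cm / m.height_cm == pytest.approx(ratio, rel=1e-12)
        assert f.weight_kg / m.weight_kg == pytest.approx(ratio**3, rel=1e-12)

    def test_cubic_law(self):
        m = full_landmark_box(height=170.0)
        h0, v0 = estimate_height(m), mesh_volume(m)
        rng = np.random.default_rng(3)
        for s in rng.uniform(0.1, 10.0, 5):
            scaled = m.copy()
            scaled.vertices = scaled.vertices * s
            assert estimate_height(scaled) == pytest.approx(s * h0, rel=1e-12)
            assert mesh_volume(scaled) == pytest.approx(s**3 * v0, rel=1e-12)

    def test_rigid_invariance_of_chain(self, male_mesh):
        bm0 = measure(male_mesh, "male")
        rng = np.random.default_rng(5)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = male_mesh.copy()
        moved.vertices = male_mesh.vertices @ rot.T + rng.normal(0, 10, 3)
        bm1 = measure(moved, "male")
        assert bm1.height_cm == pytest.approx(bm0.height_cm, rel=1e-6)
        assert bm1.weight_kg == pytest.approx(bm0.weight_kg, rel=1e-6)

    def test_fallback_max_vertex_height(self, male_mesh):
        bm = measure(male_mesh, "male", fallback_max_vertex=True)
        # the apex pole IS the farthest vertex for the neutral template
        assert bm.height_cm == pytest.approx(176.1, rel=0.005)


class TestIO:
    @pytest.mark.parametrize("ext", ["obj", "ply"])
    def test_save_load_round_trip(self, male_mesh, tmp_path, ext):
        path = tmp_path / f"mesh.{ext}"
        male_mesh.save(path)
        loaded = load_mesh(path)
        assert loaded.units == "raw"
        assert loaded.landmarks == male_mesh.landmarks
        assert np.allclose(loaded.vertices, male_mesh.vertices, atol=1e-5)
        assert np.array_equal(loaded.faces, male_mesh.faces)
        bm0 = measure(male_mesh, "male")
        bm1 = measure(loaded, "male")
        assert bm1.height_cm == pytest.approx(bm0.height_cm, rel=1e-4)
        assert bm1.weight_kg == pytest.approx(bm0.weight_kg, rel=1e-4)

    def test_validate_full_contract(self, male_mesh):
        male_mesh.validate()
        assert is_watertight(male_mesh)
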