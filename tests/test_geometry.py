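import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy.spatial.transform import Rotation

from scapmorph.geometry import (
    Axis3D,
    DegenerateInputError,
    GeometryError,
    Plane,
    build_frame,
    fit_plane,
    fit_sphere,
    perimeter,
    project_point,
    projected_angle,
)


def _sphere_points(rng, center, radius, n):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v


class TestFitSphere:
    def test_exact_unit_sphere(self):
        pts = np.array([
            [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]
        ], dtype=float)
        c, r = fit_sphere(pts)
        assert np.allclose(c, 0.0, atol=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_noisy_sphere_matches_geometric_least_squares(self, rng):
        center, radius = np.array([3.0, -2.0, 5.0]), 24.0
        pts = _sphere_points(rng, center, radius, 200)
        pts = pts + rng.normal(0.0, 0.1, pts.shape)
        c, r = fit_sphere(pts)
        assert np.linalg.norm(c - center) < 0.05

        # independent oracle: full iterative geometric least squares
        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        sol = optimize.least_squares(
            resid, np.append(pts.mean(axis=0), 20.0), method="lm"
        )
        assert np.linalg.norm(c - sol.x[:3]) < 1e-3
        assert r == pytest.approx(sol.x[3], abs=1e-3)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(DegenerateInputError, match="coplanar"):
            fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_sphere(np.eye(3))


class TestFitPlane:
    def test_exact_plane(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 3, 0]], dtype=float)
        pl = fit_plane(pts)
        assert abs(abs(pl.normal[2]) - 1.0) < 1e-12

    def test_orientation_argument_fixes_sign(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        pl = fit_plane(pts, orient=[0, 0, -1])
        assert pl.normal[2] < 0

    def test_noisy_plane_normal_within_half_degree(self, rng):
        normal = np.array([1.0, 2.0, 2.0]) / 3.0
        e1 = np.array([2.0, -1.0, 0.0]) / np.sqrt(5)
        e2 = np.cross(normal, e1)
        uv = rng.uniform(-30, 30, size=(120, 2))
        pts = uv[:, :1] * e1 + uv[:, 1:] * e2 + rng.normal(0, 0.2, (120, 1)) * normal
        pl = fit_plane(pts, orient=normal)
        ang = np.degrees(np.arccos(np.clip(pl.normal @ normal, -1, 1)))
        assert ang < 0.5
        # eigen-decomposition oracle for the same total-least-squares plane
        cov = np.cov((pts - pts.mean(axis=0)).T)
        w, v = np.linalg.eigh(cov)
        oracle = v[:, 0] * np.sign(v[:, 0] @ normal)
        assert np.degrees(np.arccos(np.clip(pl.normal @ oracle, -1, 1))) < 1e-6

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        with pytest.raises(DegenerateInputError, match="collinear"):
            fit_plane(pts)

    def test_two_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_plane(np.array([[0, 0, 0], [1, 0, 0]], dtype=float))


class TestBuildFrame:
    C = np.zeros(3)
    M = np.array([100.0, 0.0, 0.0])
    I = np.array([60.0, 0.0, -120.0])

    def test_canonical_right_frame(self):
        f = build_frame(self.C, self.M, self.I, side="right")
        assert np.allclose(f.x_hat, [1, 0, 0], atol=1e-12)
        assert abs(abs(f.y_hat[1]) - 1.0) < 1e-12
        assert np.allclose(f.z_hat, [0, 0, 1], atol=1e-12)  # superior, (I-C)·ẑ < 0

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_orthonormal_to_1e9(self, side):
        f = build_frame(self.C, self.M, self.I, side=side)
        R = f.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)

    def test_rigid_equivariance(self, rng):
        f0 = build_frame(self.C, self.M, self.I)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-50, 50, 3)
            f1 = build_frame(R @ self.C + t, R @ self.M + t, R @ self.I + t)
            for ax in ("x_hat", "y_hat", "z_hat"):
                assert np.allclose(getattr(f1, ax), R @ getattr(f0, ax), atol=1e-9)

    def test_anterior_hint_overrides_side(self):
        f = build_frame(self.C, self.M, self.I, side="right", anterior_hint=[0, -1, 0])
        assert f.y_hat[1] < 0

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_frame(self.C, self.M, np.array([50.0, 0.0, 0.0]))


class TestProjection:
    plane = Plane(point=[1.0, 2.0, 3.0], normal=[0.0, 0.0, 1.0])

    def test_in_plane_point_reproduced(self):
        p = np.array([4.0, 7.0, 3.0])
        uv = project_point(p, self.plane)
        e1, e2 = self.plane.basis()
        rec = self.plane.point + uv[0] * e1 + uv[1] * e2
        assert np.allclose(rec, p, atol=1e-12)

    def test_normal_displacement_invisible(self):
        p = np.array([4.0, 7.0, 3.0])
        assert np.allclose(
            project_point(p, self.plane),
            project_point(p + np.array([0, 0, 11.0]), self.plane),
            atol=1e-12,
        )

    def test_roundtrip_error_is_normal_only(self, rng):
        for _ in range(10):
            p = rng.uniform(-50, 50, 3)
            uv = project_point(p, self.plane)
            e1, e2 = self.plane.basis()
            rec = self.plane.point + uv[0] * e1 + uv[1] * e2
            resid = p - rec
            in_plane = resid - (resid @ self.plane.normal) * self.plane.normal
            assert np.linalg.norm(in_plane) < 1e-10


class TestProjectedAngle:
    view = Plane(point=np.zeros(3), normal=[0.0, 1.0, 0.0])

    def test_identical_axes_zero(self):
        a = Axis3D(anchor=np.zeros(3), direction=[1, 0, 1])
        assert projected_angle(a, a, self.view) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_about_normal_gives_signed_angle(self):
        ref = np.array([1.0, 0.0, 0.0])
        R = Rotation.from_rotvec(np.radians(10.0) * np.array([0, 1, 0])).as_matrix()
        assert projected_angle(R @ ref, ref, self.view) == pytest.approx(10.0, abs=1e-9)

    def test_matches_2d_atan2_oracle(self, rng):
        n = self.view.normal
        e1, e2 = self.view.basis()
        for _ in range(50):
            a, b = rng.normal(size=3), rng.normal(size=3)
            if min(np.linalg.norm(a - (a @ n) * n), np.linalg.norm(b - (b @ n) * n)) < 0.1:
                continue
            got = projected_angle(a, b, self.view)
            a2 = np.array([a @ e1, a @ e2])
            b2 = np.array([b @ e1, b @ e2])
            want = np.degrees(
                np.arctan2(b2[0] * a2[1] - b2[1] * a2[0], a2 @ b2)
            )
            if want <= -90:
                want += 180
            elif want > 90:
                want -= 180
            assert got == pytest.approx(want, abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=3), rng.normal(size=3)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        pa = a - (a @ n) * n
        pb = b - (b @ n) * n
        if min(np.linalg.norm(pa), np.linalg.norm(pb)) < 1e-2:
            return
        view = Plane(point=np.zeros(3), normal=n)
        ang0 = projected_angle(a, b, view)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        ang1 = projected_angle(R @ a, R @ b, Plane(point=t, normal=R @ n))
        assert ang1 == pytest.approx(ang0, abs=1e-9)

    def test_perpendicular_direction_rejected(self):
        with pytest.raises(GeometryError):
            projected_angle([0.0, 1.0, 0.0], [1.0, 0.0, 0.0], self.view)


class TestPerimeter:
    def test_3_4_5_triangle(self):
        w = perimeter([0, 0, 0], [3, 0, 0], [0, 4, 0])
        assert (w.cm_mm, w.mi_mm, w.ci_mm, w.s_mm) == (3.0, 5.0, 4.0, 12.0)

    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(0.1, 100.0))
    def test_uniform_scaling(self, k):
        base = perimeter([0, 0, 0], [3, 0, 0], [0, 4, 0])
        scaled = perimeter([0, 0, 0], [3 * k, 0, 0], [0, 4 * k, 0])
        assert scaled.s_mm == pytest.approx(k * base.s_mm, rel=1e-12)

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(DegenerateInputError):
            perimeter([0, 0, 0], [0, 0, 0], [0, 4, 0])
        with pytest.raises(DegenerateInputError):
            perimeter([0, 0, 0], [1, 0, 0], [2, 0, 0])
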