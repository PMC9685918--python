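"""Reference-frame construction and projective angle measurement.

The scapular coordinate system follows the convention used throughout the
package: the origin sits at the glenoid centre C, ``x_hat`` points from C to
the spine/medial-border junction M (medial), ``y_hat`` is the scapular-plane
normal oriented anteriorly and ``z_hat`` completes the frame pointing
superiorly.  All angular morphometrics are signed angles measured between
orthographic projections of 3D axes into one of the three reference planes,
which replaces a manual "viewing plane" workflow with deterministic linear
algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "GeometryError",
    "DegenerateInputError",
    "Plane",
    "Axis3D",
    "ScapularFrame",
    "WeightingPerimeter",
    "fit_sphere",
    "fit_plane",
    "build_frame",
    "project_point",
    "projected_angle",
    "perimeter",
]


class GeometryError(ValueError):
    """Base class for geometric contract violations."""


class DegenerateInputError(GeometryError):
    """Raised when input points are collinear/coplanar/coincident."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateInputError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal))

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """A deterministic right-handed in-plane 2D basis (e1, e2).

        e1 is the normalized projection of the global axis least aligned
        with the normal; e2 = normal x e1.
        """
        n = self.normal
        seed = np.eye(3)[int(np.argmin(np.abs(n)))]
        e1 = _unit(seed - (seed @ n) * n)
        e2 = np.cross(n, e1)
        return e1, e2


@dataclass(frozen=True)
class Axis3D:
    """A line in space: anchor point plus unit direction."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction))

    @classmethod
    def through(cls, a: np.ndarray, b: np.ndarray) -> "Axis3D":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return cls(anchor=a, direction=b - a)


@dataclass(frozen=True)
class ScapularFrame:
    """Scapular reference frame anchored at the glenoid centre C.

    Attributes
    ----------
    origin : point C (mm).
    x_hat : unit vector along C -> M (medial).
    y_hat : scapular-plane normal, oriented anteriorly.
    z_hat : in-plane superoinferior axis, oriented superiorly.
    side : "left" or "right".  Left frames are mirror images of right
        frames, so the (x̂, ŷ, ẑ) triad of a left scapula is left-handed;
        orthonormality always holds.
    """

    origin: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    z_hat: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        for name in ("x_hat", "y_hat", "z_hat"):
            object.__setattr__(self, name, _unit(getattr(self, name)))

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are (x̂, ŷ, ẑ): maps world -> frame coords."""
        return np.vstack([self.x_hat, self.y_hat, self.z_hat])

    def to_frame(self, pts: np.ndarray) -> np.ndarray:
        """Express world points in frame coordinates (mm)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) @ self.rotation.T

    def to_world(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation + self.origin

    def direction_to_frame(self, d: np.ndarray) -> np.ndarray:
        return np.asarray(d, dtype=float) @ self.rotation.T

    # The three reference (viewing) planes.
    @property
    def scapular_plane(self) -> Plane:
        """Plane through C, M, I (normal ŷ): the baseline coronal-like view."""
        return Plane(self.origin, self.y_hat)

    @property
    def axial_plane(self) -> Plane:
        """Transverse plane (normal ẑ): the axial view."""
        return Plane(self.origin, self.z_hat)

    @property
    def sagittal_plane(self) -> Plane:
        """Plane normal to x̂: the sagittal view."""
        return Plane(self.origin, self.x_hat)


@dataclass(frozen=True)
class WeightingPerimeter:
    """Pairwise distances among C, M, I and their sum.

    Every linear morphometric is divided by ``s_mm`` to remove body-size
    effects ("wt" quantities are dimensionless).
    """

    cm_mm: float
    mi_mm: float
    ci_mm: float
    s_mm: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("cm_mm", "mi_mm", "ci_mm"):
            if getattr(self, name) <= 0.0:
                raise DegenerateInputError(f"{name} must be > 0")
        a, b, c = self.cm_mm, self.mi_mm, self.ci_mm
        if a + b <= c or b + c <= a or a + c <= b:
            raise DegenerateInputError("C, M, I violate the triangle inequality")
        object.__setattr__(self, "s_mm", a + b + c)

    def weight(self, length_mm: float) -> float:
        return float(length_mm) / self.s_mm


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit (algebraic solve + one Gauss-Newton step).

    Parameters
    ----------
    points : (n, 3) array, n >= 4, not all coplanar.

    Returns
    -------
    center : (3,) array; radius : float.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 4 or pts.shape[1] != 3:
        raise DegenerateInputError("sphere fit needs at least 4 points in 3D")
    # Algebraic form |p|^2 = 2 p.c + (r^2 - |c|^2).
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    # Coplanarity check: rank of centred points must be 3.
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 3:
        raise DegenerateInputError("points are coplanar; sphere is not determined")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateInputError("degenerate sphere fit (non-positive radius)")
    radius = float(np.sqrt(r2))

    # One Gauss-Newton step on the geometric residuals r_i = |p_i - c| - R.
    def residuals(x):
        c, R = x[:3], x[3]
        return np.linalg.norm(pts - c, axis=1) - R

    x0 = np.append(center, radius)
    res = optimize.least_squares(residuals, x0, max_nfev=3, method="lm")
    center, radius = res.x[:3], float(res.x[3])
    if radius <= 0:
        raise DegenerateInputError("sphere fit collapsed to non-positive radius")
    return center, radius


def fit_plane(points: np.ndarray, orient: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through ``points`` (SVD, smallest component).

    ``orient`` optionally fixes the normal sign so that normal . orient > 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateInputError("plane fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    scale = max(1.0, float(s[0]))
    if s[1] < 1e-9 * scale:
        raise DegenerateInputError("points are collinear; plane is not determined")
    normal = vt[2]
    if orient is not None:
        d = float(np.asarray(orient, dtype=float) @ normal)
        if d < 0:
            normal = -normal
    return Plane(centroid, normal)


def build_frame(
    C: np.ndarray,
    M: np.ndarray,
    I: np.ndarray,
    side: str = "right",
    anterior_hint: np.ndarray | None = None,
) -> ScapularFrame:
    """Construct the scapular frame from the three blade landmarks.

    x̂ = unit(M − C).  ŷ is the normal of plane(C, M, I); with I inferior the
    cross product (M−C)×(I−C) points anteriorly for a right scapula and
    posteriorly for a left one, so the sign is flipped for left sides (or
    fixed by ``anterior_hint`` when supplied).  ẑ = ±x̂×ŷ with the sign chosen
    so that (I−C)·ẑ < 0, i.e. ẑ points superiorly.
    """
    C = np.asarray(C, dtype=float)
    M = np.asarray(M, dtype=float)
    I = np.asarray(I, dtype=float)
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    x_hat = _unit(M - C)
    n = np.cross(M - C, I - C)
    if np.linalg.norm(n) < 1e-9 * max(np.linalg.norm(M - C), 1.0):
        raise DegenerateInputError("C, M, I are collinear; frame undefined")
    y_hat = _unit(n)
    if anterior_hint is not None:
        if float(np.asarray(anterior_hint, dtype=float) @ y_hat) < 0:
            y_hat = -y_hat
    elif side == "left":
        y_hat = -y_hat
    z_hat = np.cross(x_hat, y_hat)
    if float((I - C) @ z_hat) > 0:
        z_hat = -z_hat
    return ScapularFrame(origin=C, x_hat=x_hat, y_hat=y_hat, z_hat=z_hat, side=side)


def project_point(
    p: np.ndarray,
    viewing_plane: Plane,
    basis: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Orthographic projection of ``p`` into a viewing plane.

    Returns the 2D coordinates of the projection in the plane's basis
    (``viewing_plane.basis()`` unless an explicit in-plane basis is given).
    Distances parallel to the plane are preserved exactly.
    """
    e1, e2 = basis if basis is not None else viewing_plane.basis()
    rel = np.asarray(p, dtype=float) - viewing_plane.point
    return np.array([rel @ e1, rel @ e2])


def projected_angle(
    a: "Axis3D | np.ndarray",
    ref: "Axis3D | np.ndarray",
    viewing_plane: Plane,
    signed: bool = True,
) -> float:
    """Signed angle (degrees) between two axes after projection into a view.

    Both directions are projected orthographically into ``viewing_plane``;
    the angle is measured counterclockwise from ``ref`` to ``a`` when looking
    along the plane normal, and folded into (−90°, 90°] because axes are
    undirected lines.  Raises if either direction is (numerically)
    perpendicular to the viewing plane.
    """
    da = a.direction if isinstance(a, Axis3D) else _unit(a)
    dr = ref.direction if isinstance(ref, Axis3D) else _unit(ref)
    n = viewing_plane.normal
    pa = da - (da @ n) * n
    pr = dr - (dr @ n) * n
    if np.linalg.norm(pa) < 1e-6 or np.linalg.norm(pr) < 1e-6:
        raise GeometryError("direction is perpendicular to the viewing plane")
    pa /= np.linalg.norm(pa)
    pr /= np.linalg.norm(pr)
    cross = float(n @ np.cross(pr, pa))
    dot = float(pr @ pa)
    ang = float(np.degrees(np.arctan2(cross, dot)))
    # Fold to (−90, 90] under line (not ray) identification.
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    if not signed:
        ang = abs(ang)
    return ang


def perimeter(C: np.ndarray, M: np.ndarray, I: np.ndarray) -> WeightingPerimeter:
    """Pairwise distances CM, MI, CI and their sum s = CM + MI + CI."""
    C = np.asarray(C, dtype=float)
    M = np.asarray(M, dtype=float)
    I = np.asarray(I, dtype=float)
    return WeightingPerimeter(
        cm_mm=float(np.linalg.norm(M - C)),
        mi_mm=float(np.linalg.norm(I - M)),
        ci_mm=float(np.linalg.norm(I - C)),
    )
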