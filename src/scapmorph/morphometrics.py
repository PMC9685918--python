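"""Critical shoulder angle and the 17 explanatory morphometrics.

All measurements are taken in the scapular frame: angular quantities are
signed projected angles (degrees) in one of the three reference views, and
linear quantities are divided by the blade perimeter s = CM + MI + CI
("wt", dimensionless) so they are invariant to body size.

Sign table
----------
GI    : + = superior inclination: the glenoid face tips superiorly, its
        superior rim moving medially (consistent with CSA growing with GI).
GV    : + = anteversion, − = retroversion (axial rotation of the face).
CPAA  : + = lateral acromion rotated superiorly about the longitudinal
        acromial axis (consistent with CSA falling as CPAA grows).
SPAA/APAA, CPSSA/SPSSA/APSSA : raw counterclockwise projected angles in the
sagittal/axial/scapular views, folded to (−90°, 90°]; the neutral-value
convention is documented rather than re-zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import trimesh
from scipy import optimize
from shapely.geometry import Polygon, box as shapely_box
from shapely.ops import unary_union

from .geometry import (
    Axis3D,
    GeometryError,
    Plane,
    ScapularFrame,
    WeightingPerimeter,
    build_frame,
    fit_plane,
    perimeter,
    projected_angle,
)
from .landmarks import AcromialBox, LandmarkSet, build_acromial_box, derive_acromial_axes

__all__ = [
    "MeasurementError",
    "MorphometricRecord",
    "RECORD_COLUMNS",
    "measure_gi",
    "measure_gv",
    "measure_csa",
    "measure_acromial_geometry",
    "measure_acromial_orientation",
    "measure_spine",
    "measure_spinoglenoid_distances",
    "assemble_record",
]

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])
_O = np.zeros(3)

# Reference viewing planes in frame coordinates.
_SCAPULAR_VIEW = Plane(_O, _EY)
_AXIAL_VIEW = Plane(_O, _EZ)
_SAGITTAL_VIEW = Plane(_O, _EX)


class MeasurementError(GeometryError):
    """A morphometric could not be computed; the message names it."""


# Record field -> column name as printed in the cohort table header.
RECORD_COLUMNS: dict[str, str] = {
    "gi_deg": "Glenoid inclination (deg)",
    "gv_deg": "Glenoid version (deg)",
    "acr_box_width_wt": "Acromial Box Width wt",
    "ant_acr_box_length_wt": "Anterior Acromial Box Length wt",
    "post_acr_box_length_wt": "Posterior Acromial Box Length wt",
    "ant_acr_box_area": "Anterior Acromial Box Area",
    "post_acr_box_area": "Posterior Acromial Box Area",
    "apaa_deg": "Axial plane angulation of the acromion (deg)",
    "spaa_deg": "Sagittal plane angulation of the acromion (deg)",
    "cpaa_deg": "Coronal plane angulation of the acromion (deg)",
    "spinal_length_wt": "Spinal Length Wt",
    "cpssa_deg": "Coronal plane scapula spine angulation (deg)",
    "apssa_deg": "Axial plane scapula spine angulation (deg)",
    "spssa_deg": "Sagittal plane scapula spine angulation (deg)",
    "sg_dist_x_wt": "Spinoglenoid distance x plane wt",
    "sg_dist_y_wt": "Spinoglenoid distance y plane wt",
    "sg_dist_z_wt": "Spinoglenoid distance z plane wt",
}
OUTCOME_COLUMN = "CSA"


@dataclass(frozen=True)
class MorphometricRecord:
    """CSA plus the 17 explanatory variables for one scapula."""

    csa_deg: float
    gi_deg: float
    gv_deg: float
    acr_box_width_wt: float
    ant_acr_box_length_wt: float
    post_acr_box_length_wt: float
    ant_acr_box_area: float
    post_acr_box_area: float
    cpaa_deg: float
    spaa_deg: float
    apaa_deg: float
    spinal_length_wt: float
    cpssa_deg: float
    spssa_deg: float
    apssa_deg: float
    sg_dist_x_wt: float
    sg_dist_y_wt: float
    sg_dist_z_wt: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if not np.isfinite(v):
                raise MeasurementError(f"{f.name} is not finite")
        for name in (
            "acr_box_width_wt", "ant_acr_box_length_wt",
            "post_acr_box_length_wt", "spinal_length_wt",
            "sg_dist_x_wt", "sg_dist_y_wt", "sg_dist_z_wt",
        ):
            if getattr(self, name) < 0:
                raise MeasurementError(f"{name} must be >= 0")
        for name in ("ant_acr_box_area", "post_acr_box_area"):
            if not (-1e-9 <= getattr(self, name) <= 1.0 + 1e-9):
                raise MeasurementError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict[str, float]:
        d = {OUTCOME_COLUMN: self.csa_deg}
        d.update({col: getattr(self, f) for f, col in RECORD_COLUMNS.items()})
        return d


def _rim_line(landmarks: LandmarkSet, frame: ScapularFrame, which: str) -> np.ndarray:
    a = getattr(landmarks, f"rim_{which[0]}")
    b = getattr(landmarks, f"rim_{which[1]}")
    if a is None or b is None:
        raise MeasurementError(f"glenoid rim points for {which} are missing")
    a = frame.to_frame(a)
    b = frame.to_frame(b)
    if np.linalg.norm(a - b) < 1e-9:
        raise MeasurementError("degenerate glenoid rim line")
    return a - b


def measure_gi(landmarks: LandmarkSet, frame: ScapularFrame) -> float:
    """Glenoid inclination: angle of the superoinferior glenoid line vs ẑ in
    the scapular-plane view; positive when the face is superiorly inclined
    (superior rim displaced medially)."""
    u = _rim_line(landmarks, frame, ("superior", "inferior"))
    if u[2] < 0:
        u = -u
    ux, uz = u[0], u[2]
    if abs(ux) < 1e-12 and abs(uz) < 1e-12:
        raise MeasurementError("glenoid line is perpendicular to the scapular plane")
    return float(np.degrees(np.arctan2(ux, uz)))


def measure_gv(
    landmarks: LandmarkSet,
    frame: ScapularFrame,
    bracket_deg: float = 44.0,
) -> float:
    """Glenoid version: the signed rotation about ẑ that brings the anterior
    and posterior rim points into optimal overlap in the projected view
    (the Suter–Henninger A1 condition); negative = retroversion."""
    d = _rim_line(landmarks, frame, ("anterior", "posterior"))

    def separation(theta_deg: float) -> float:
        th = np.radians(theta_deg)
        v = np.array([np.sin(th), np.cos(th), 0.0])
        resid = d - (d @ v) * v
        return float(resid @ resid)

    res = optimize.minimize_scalar(
        separation, bounds=(-bracket_deg, bracket_deg), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise MeasurementError("glenoid version minimization failed to bracket")
    return float(res.x)


def _a1_basis(gv_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    th = np.radians(gv_deg)
    v = np.array([np.sin(th), np.cos(th), 0.0])  # viewing direction
    e1 = np.cross(_EZ, v)
    e1 /= np.linalg.norm(e1)
    return v, e1, _EZ


def csa_from_points(
    rim_inferior: np.ndarray,
    rim_superior: np.ndarray,
    acromial_points: np.ndarray,
    gv_deg: float,
) -> float:
    """2D CSA in the A1 view from frame-coordinate points.

    The acromial landmark is the projected vertex that maximizes the angle
    at the inferior glenoid point (tangent rule); ties break toward the
    most inferior vertex.
    """
    acromial_points = np.atleast_2d(np.asarray(acromial_points, dtype=float))
    if len(acromial_points) == 0:
        raise MeasurementError("empty acromial vertex set for the CSA")
    _, e1, e2 = _a1_basis(gv_deg)

    def p2(p):
        p = np.asarray(p, dtype=float)
        return np.stack([p @ e1, p @ e2], axis=-1)

    inf2 = p2(rim_inferior)
    sup2 = p2(rim_superior)
    ac2 = p2(acromial_points)
    a = sup2 - inf2
    na = np.linalg.norm(a)
    if na < 1e-9:
        raise MeasurementError("degenerate glenoid line in the A1 view")
    b = ac2 - inf2
    nb = np.linalg.norm(b, axis=1)
    ok = nb > 1e-9
    if not np.any(ok):
        raise MeasurementError("acromial vertices coincide with the inferior glenoid")
    cosang = np.clip((b[ok] @ a) / (nb[ok] * na), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    best = ang.max()
    cand = np.where(ang > best - 1e-9)[0]
    # tie-break: most inferior (smallest projected z)
    z2 = ac2[ok][cand, 1]
    return float(ang[cand[int(np.argmin(z2))]])


def measure_csa(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    frame: ScapularFrame,
    box: AcromialBox,
    gv_deg: float | None = None,
    slab_mm: float = 1.5,
) -> float:
    """Critical shoulder angle in the A1 view (degrees).

    The viewing direction is the baseline view rotated about ẑ by the
    measured glenoid version; acromial candidates are the mesh vertices on
    the acromial undersurface (within ``slab_mm`` of the undersurface plane
    and inside the acromial box footprint)."""
    if gv_deg is None:
        gv_deg = measure_gv(landmarks, frame)
    h = box.under_plane.signed_distance(mesh.vertices)
    t = box.mid_plane.signed_distance(mesh.vertices)
    l = box.as_plane.signed_distance(mesh.vertices)
    keep = (
        (np.abs(h) < slab_mm)
        & (t > -box.width_mm - 2.0) & (t < 2.0)
        & (l > -box.post_length_mm - 2.0) & (l < box.ant_length_mm + 2.0)
    )
    acr = mesh.vertices[keep]
    if len(acr) == 0:
        raise MeasurementError("empty acromial vertex set for the CSA")
    if landmarks.rim_inferior is None or landmarks.rim_superior is None:
        raise MeasurementError("glenoid rim points are missing for the CSA")
    return csa_from_points(
        frame.to_frame(landmarks.rim_inferior),
        frame.to_frame(landmarks.rim_superior),
        frame.to_frame(acr),
        gv_deg,
    )


def _silhouette_fill(
    mesh: trimesh.Trimesh, box: AcromialBox, u0: float, u1: float
) -> float:
    """Fill fraction of the bone silhouette within a sub-box, in the
    undersurface projection.  u is the longitudinal coordinate (mm from the
    AS plane, anterior positive), spanning [u0, u1]."""
    AS = box.as_plane.point
    l_dir = box.longitudinal_dir
    t_dir = box.transverse_dir
    h = box.under_plane.signed_distance(mesh.vertices)
    in_slab = (h > -2.0) & (h < 0.5 * max(box.width_mm, 10.0))
    vmask = np.zeros(len(mesh.vertices), dtype=bool)
    vmask[in_slab] = True
    fmask = vmask[mesh.faces].all(axis=1)
    tris = mesh.vertices[mesh.faces[fmask]]
    if len(tris) == 0:
        return 0.0
    rel = tris - AS
    u = rel @ l_dir
    v = -(rel @ t_dir)  # 0 at mid plane, +width at lateral border
    polys = []
    for i in range(len(tris)):
        p = Polygon(np.stack([u[i], v[i]], axis=1))
        if p.is_valid and p.area > 1e-12:
            polys.append(p)
    if not polys:
        return 0.0
    sil = unary_union(polys)
    rect = shapely_box(u0, 0.0, u1, box.width_mm)
    fill = sil.intersection(rect).area / rect.area
    return float(min(max(fill, 0.0), 1.0))


def measure_acromial_geometry(
    box: AcromialBox,
    mesh: trimesh.Trimesh,
    perim: WeightingPerimeter,
) -> tuple[float, float, float, float, float]:
    """Weighted box width and lengths plus the two sub-box fill areas.

    Areas are the fraction of each sub-box covered by the projected bone
    silhouette in the undersurface view (dimensionless, in [0, 1])."""
    width_wt = perim.weight(box.width_mm)
    ant_wt = perim.weight(box.ant_length_mm)
    post_wt = perim.weight(box.post_length_mm)
    ant_area = _silhouette_fill(mesh, box, 0.0, box.ant_length_mm)
    post_area = _silhouette_fill(mesh, box, -box.post_length_mm, 0.0)
    return width_wt, ant_wt, post_wt, ant_area, post_area


def measure_acromial_orientation(
    llap_axis: Axis3D,
    tlap_axis: Axis3D,
    frame: ScapularFrame,
) -> tuple[float, float, float]:
    """(CPAA, SPAA, APAA) in degrees from the two lateral acromial axes.

    APAA: longitudinal axis vs ŷ in the axial view.  SPAA: longitudinal axis
    vs ẑ in the sagittal view.  CPAA: transverse axis vs x̂ in the
    scapular-plane view (positive = lateral acromion rotated superiorly)."""
    llap = frame.direction_to_frame(llap_axis.direction)
    tlap = frame.direction_to_frame(tlap_axis.direction)
    apaa = projected_angle(llap, _EY, _AXIAL_VIEW)
    spaa = projected_angle(llap, _EZ, _SAGITTAL_VIEW)
    cpaa = projected_angle(tlap, _EX, _SCAPULAR_VIEW)
    return cpaa, spaa, apaa


def spine_angles_from_direction(d_frame: np.ndarray) -> tuple[float, float, float]:
    """(CPSSA, SPSSA, APSSA) of a spinal-axis direction in frame coords."""
    cpssa = projected_angle(d_frame, _EX, _SCAPULAR_VIEW)
    spssa = projected_angle(d_frame, _EZ, _SAGITTAL_VIEW)
    apssa = projected_angle(d_frame, _EY, _AXIAL_VIEW)
    return cpssa, spssa, apssa


def measure_spine(
    landmarks: LandmarkSet,
    frame: ScapularFrame,
    perim: WeightingPerimeter,
) -> tuple[float, float, float, float]:
    """(spinal_length_wt, CPSSA, SPSSA, APSSA) from the M→AS spinal axis."""
    if landmarks.AS is None:
        raise MeasurementError("AS point is missing for the spine measurements")
    m = frame.to_frame(landmarks.M)
    a = frame.to_frame(landmarks.AS)
    d = a - m
    length = float(np.linalg.norm(d))
    if length < 1e-9:
        raise MeasurementError("M and AS coincide; spinal axis undefined")
    cpssa, spssa, apssa = spine_angles_from_direction(d / length)
    return perim.weight(length), cpssa, spssa, apssa


def measure_spinoglenoid_distances(
    SG: np.ndarray,
    frame: ScapularFrame,
    perim: WeightingPerimeter,
) -> tuple[float, float, float]:
    """Absolute components of SG − C along (x̂, ŷ, ẑ), each divided by s."""
    rel = frame.to_frame(SG)
    return tuple(perim.weight(abs(float(c))) for c in rel)  # type: ignore[return-value]


def assemble_record(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    frame: ScapularFrame | None = None,
) -> MorphometricRecord:
    """Compute the full morphometric record for one mesh.

    Requires AS, SG, the named glenoid rim points and the acromial patches
    to be present in ``landmarks`` (generator truth or annotations).
    Deterministic given its inputs; sub-measurement failures propagate with
    the failing measurement named.
    """
    if frame is None:
        frame = build_frame(
            landmarks.C, landmarks.M, landmarks.I,
            side=landmarks.side, anterior_hint=landmarks.anterior_hint,
        )
    perim = perimeter(landmarks.C, landmarks.M, landmarks.I)

    def run(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise MeasurementError(f"{name}: {exc}") from exc

    gi = run("glenoid inclination", measure_gi, landmarks, frame)
    gv = run("glenoid version", measure_gv, landmarks, frame)
    if landmarks.AS is None or landmarks.SG is None:
        raise MeasurementError("AS/SG landmarks are required; run the locators first")
    if landmarks.lateral_border_patch is None or landmarks.acromion_under_patch is None:
        raise MeasurementError("acromial patches are required for the box construction")
    acrbox = run(
        "acromial box", build_acromial_box,
        mesh, frame, landmarks.AS,
        landmarks.lateral_border_patch, landmarks.acromion_under_patch,
    )
    llap, tlap = run("acromial axes", derive_acromial_axes, acrbox, mesh)
    acrbox = replace(acrbox, llap_axis=llap, tlap_axis=tlap)
    width_wt, ant_wt, post_wt, ant_area, post_area = run(
        "acromial geometry", measure_acromial_geometry, acrbox, mesh, perim
    )
    cpaa, spaa, apaa = run(
        "acromial orientation", measure_acromial_orientation, llap, tlap, frame
    )
    csa = run("CSA", measure_csa, mesh, landmarks, frame, acrbox, gv)
    sp_wt, cpssa, spssa, apssa = run("spine", measure_spine, landmarks, frame, perim)
    sgx, sgy, sgz = run(
        "spinoglenoid distances", measure_spinoglenoid_distances,
        landmarks.SG, frame, perim,
    )
    return MorphometricRecord(
        csa_deg=csa, gi_deg=gi, gv_deg=gv,
        acr_box_width_wt=width_wt,
        ant_acr_box_length_wt=ant_wt,
        post_acr_box_length_wt=post_wt,
        ant_acr_box_area=ant_area,
        post_acr_box_area=post_area,
        cpaa_deg=cpaa, spaa_deg=spaa, apaa_deg=apaa,
        spinal_length_wt=sp_wt,
        cpssa_deg=cpssa, spssa_deg=spssa, apssa_deg=apssa,
        sg_dist_x_wt=sgx, sg_dist_y_wt=sgy, sg_dist_z_wt=sgz,
    )
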