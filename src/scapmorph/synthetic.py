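"""Parametric synthetic scapulae, cohort tables and screening logs.

The mesh generator builds a scapula-like surface with fully analytic ground
truth: a thin triangular blade through C, M, I (the scapular plane); a
spherical-cap glenoid realizing prescribed inclination and version exactly;
a prismatic spine body passing through the spinoglenoid (SG) point with a
notch pit below it; an acromial plate realizing the prescribed box geometry
with the coronal-plane angulation realized exactly and the remaining
orientation angles realized through a documented rotation recipe; and a
v-shaped junction ridge terminating at the acromiospinal (AS) point on the
plate undersurface.  Geometry is constructed in the canonical scapular frame
and a seeded random rigid transform is applied before the mesh is emitted,
so downstream frame construction is genuinely exercised.  Left scapulae are
mirror images of the right-side construction; ground truth is
side-invariant.

The cohort generator draws 17 predictors from a multivariate normal with
controllable collinear groups and builds the critical shoulder angle (CSA)
from a known linear model, giving model selection a known active set to
recover.  The screening-log generator emits records violating each exclusion
criterion a prescribed number of times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon

from .geometry import Plane, projected_angle
from .landmarks import LandmarkSet
from .morphometrics import (
    MorphometricRecord,
    RECORD_COLUMNS,
    OUTCOME_COLUMN,
    csa_from_points,
    spine_angles_from_direction,
)

__all__ = [
    "InfeasibleParamsError",
    "ScapulaParams",
    "GroundTruth",
    "CohortSimSpec",
    "CohortTruth",
    "ScreeningRecord",
    "generate_scapula",
    "sample_scapula_params",
    "generate_cohort_table",
    "generate_screening_log",
    "COHORT_MEANS",
    "COHORT_SDS",
    "body_scale_for_perimeter",
]

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])

# Blade triangle shape: M = (1, 0, 0)·bs, I = (0.6, 0, −1.2)·bs, so the
# perimeter s = CM + MI + CI is a fixed multiple of the body scale.
_I_SHAPE = np.array([0.6, 0.0, -1.2])
PERIMETER_FACTOR = 1.0 + math.sqrt(1.6) + math.sqrt(1.8)

# Descriptive statistics printed for the 17 explanatory variables (used as
# realistic defaults and cohort marginals).  The printed dispersion for
# glenoid version is unusable (a negative value), so a plausible 4.0° is
# substituted there.
COHORT_MEANS: dict[str, float] = {
    "Glenoid inclination (deg)": 7.14,
    "Glenoid version (deg)": -4.75,
    "Acromial Box Width wt": 0.14,
    "Anterior Acromial Box Length wt": 0.30,
    "Posterior Acromial Box Length wt": 0.12,
    "Anterior Acromial Box Area": 0.77,
    "Posterior Acromial Box Area": 0.62,
    "Axial plane angulation of the acromion (deg)": 65.12,
    "Sagittal plane angulation of the acromion (deg)": 61.23,
    "Coronal plane angulation of the acromion (deg)": 7.16,
    "Spinal Length Wt": 0.29,
    "Coronal plane scapula spine angulation (deg)": 37.96,
    "Axial plane scapula spine angulation (deg)": 35.61,
    "Sagittal plane scapula spine angulation (deg)": 42.66,
    "Spinoglenoid distance x plane wt": 0.17,
    "Spinoglenoid distance y plane wt": 0.07,
    "Spinoglenoid distance z plane wt": 0.07,
}
COHORT_SDS: dict[str, float] = {
    "Glenoid inclination (deg)": 4.10,
    "Glenoid version (deg)": 4.0,
    "Acromial Box Width wt": 0.04,
    "Anterior Acromial Box Length wt": 0.04,
    "Posterior Acromial Box Length wt": 0.02,
    "Anterior Acromial Box Area": 0.10,
    "Posterior Acromial Box Area": 0.11,
    "Axial plane angulation of the acromion (deg)": 9.80,
    "Sagittal plane angulation of the acromion (deg)": 9.39,
    "Coronal plane angulation of the acromion (deg)": 15.42,
    "Spinal Length Wt": 0.04,
    "Coronal plane scapula spine angulation (deg)": 5.94,
    "Axial plane scapula spine angulation (deg)": 7.23,
    "Sagittal plane scapula spine angulation (deg)": 9.37,
    "Spinoglenoid distance x plane wt": 0.02,
    "Spinoglenoid distance y plane wt": 0.01,
    "Spinoglenoid distance z plane wt": 0.02,
}


class InfeasibleParamsError(ValueError):
    """The requested parameter combination yields impossible geometry."""


def body_scale_for_perimeter(s_mm: float) -> float:
    """Body scale giving a blade perimeter s = CM + MI + CI of ``s_mm``."""
    return float(s_mm) / PERIMETER_FACTOR


_DEFAULT_S = 100.0 * PERIMETER_FACTOR  # perimeter at the default body scale


@dataclass(frozen=True)
class ScapulaParams:
    """Generator parameters; angles in degrees, lengths in mm.

    The acromial/spinal orientation angles parametrize intrinsic Z-X-Y
    rotation recipes; because three projected angles of one axis carry only
    two degrees of freedom, the stored ground truth is always the *realized*
    projected angle (equal to the parameter whenever the other two angles of
    the triple are neutral).  The neutral value of SPAA is 90° and of APSSA
    is −90° under this package's raw-angle convention.
    """

    side: str = "right"
    gi_deg: float = 7.14
    gv_deg: float = -4.75
    cpaa_deg: float = 7.16
    spaa_deg: float = 61.23
    apaa_deg: float = 24.9
    cpssa_deg: float = 37.96
    spssa_deg: float = 10.0
    apssa_deg: float = -78.0
    glenoid_radius_mm: float = 24.0
    acromion_width_mm: float = 0.14 * _DEFAULT_S
    acromion_ant_length_mm: float = 0.30 * _DEFAULT_S
    acromion_post_length_mm: float = 0.12 * _DEFAULT_S
    acromion_corner_trim: float = 0.35
    spine_length_mm: float = 0.29 * _DEFAULT_S
    body_scale_mm: float = 100.0
    sg_offset_mm: tuple[float, float, float] = (
        0.17 * _DEFAULT_S, -0.07 * _DEFAULT_S, 0.07 * _DEFAULT_S
    )
    noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in (
            "glenoid_radius_mm", "acromion_width_mm", "acromion_ant_length_mm",
            "acromion_post_length_mm", "spine_length_mm", "body_scale_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if abs(self.gv_deg) >= 45 or abs(self.gi_deg) >= 45:
            raise ValueError("|gi_deg| and |gv_deg| must be < 45")
        if self.noise_mm < 0:
            raise ValueError("noise_mm must be >= 0")
        if not (0.0 <= self.acromion_corner_trim <= 0.9):
            raise ValueError("acromion_corner_trim must lie in [0, 0.9]")

    @property
    def perimeter_mm(self) -> float:
        return PERIMETER_FACTOR * self.body_scale_mm


@dataclass(frozen=True)
class GroundTruth:
    """Analytic ground truth accompanying a generated mesh."""

    params: ScapulaParams
    landmarks: LandmarkSet
    expected_record: MorphometricRecord

    @property
    def expected_csa_deg(self) -> float:
        return self.expected_record.csa_deg


def _plate_rotation(p: ScapulaParams) -> np.ndarray:
    """Intrinsic Z-X-Y recipe for the acromial plate (APAA, then SPAA, then
    CPAA), with the offsets making each parameter equal the realized angle
    when the other two are neutral."""
    return Rotation.from_euler(
        "ZXY", [p.apaa_deg, p.spaa_deg - 90.0, p.cpaa_deg], degrees=True
    ).as_matrix()


def _spine_direction(p: ScapulaParams) -> np.ndarray:
    """Intrinsic Z-X-Y recipe for the spinal axis (APSSA, SPSSA, CPSSA),
    applied to the neutral lateral direction −x̂."""
    R = Rotation.from_euler(
        "ZXY", [p.apssa_deg + 90.0, p.spssa_deg, p.cpssa_deg], degrees=True
    ).as_matrix()
    return R @ (-_EX)


def _glenoid_axes(p: ScapulaParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(d_sup, d_ant, n_lat) realizing GI and GV exactly.

    d_ant lies in the axial plane at angle gv from ŷ (version); d_sup is
    orthogonal to it with scapular-plane projection at angle gi from ẑ
    (inclination); n_lat = d_sup × d_ant faces laterally.
    """
    gi = math.radians(p.gi_deg)
    gv = math.radians(p.gv_deg)
    d_ant = np.array([math.sin(gv), math.cos(gv), 0.0])
    # Positive inclination tips the face superiorly: the superior rim moves
    # medially (+x), so the CSA opens with growing GI.
    d_sup = np.array([math.sin(gi), -math.sin(gi) * math.tan(gv), math.cos(gi)])
    d_sup /= np.linalg.norm(d_sup)
    n_lat = np.cross(d_sup, d_ant)
    n_lat /= np.linalg.norm(n_lat)
    return d_sup, d_ant, n_lat


def _glenoid_cap(
    p: ScapulaParams, n_rings: int = 8, n_around: int = 24, cap_deg: float = 50.0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Spherical-cap glenoid centred on the best-fit sphere centre C = 0."""
    d_sup, d_ant, n_lat = _glenoid_axes(p)
    R = p.glenoid_radius_mm
    beta_max = math.radians(cap_deg)
    alphas = np.arange(n_around) * (2.0 * math.pi / n_around)
    verts = [(-R) * n_lat]  # deepest point of the fossa
    for i in range(1, n_rings + 1):
        b = beta_max * i / n_rings
        ring = (
            -R * math.cos(b) * n_lat
            + R * math.sin(b)
            * (np.cos(alphas)[:, None] * d_sup + np.sin(alphas)[:, None] * d_ant)
        )
        verts.append(ring)
    verts = np.vstack([verts[0][None, :], *verts[1:]])
    faces = []
    for j in range(n_around):  # apex fan
        faces.append([0, 1 + j, 1 + (j + 1) % n_around])
    for i in range(n_rings - 1):
        r0 = 1 + i * n_around
        r1 = r0 + n_around
        for j in range(n_around):
            a, b = r0 + j, r0 + (j + 1) % n_around
            c, d = r1 + j, r1 + (j + 1) % n_around
            faces.append([a, c, d])
            faces.append([a, d, b])
    rim0 = 1 + (n_rings - 1) * n_around
    rim = verts[rim0: rim0 + n_around]
    info = {
        "rim": rim,
        "rim_superior": rim[0],
        "rim_anterior": rim[n_around // 4],
        "rim_inferior": rim[n_around // 2],
        "rim_posterior": rim[3 * n_around // 4],
        "face_patch": verts[1 + (n_rings // 2 - 1) * n_around:],
        "n_lat": n_lat,
    }
    return np.asarray(verts), np.asarray(faces, dtype=int), info


def _blade(p: ScapulaParams, half_t: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    bs = p.body_scale_mm
    tri = np.array([[0.0, 0.0, 0.0], _EX * bs, _I_SHAPE * bs])
    v = np.vstack([tri + _EY * half_t, tri - _EY * half_t])
    f = np.array([
        [0, 1, 2], [3, 5, 4],
        [0, 3, 4], [0, 4, 1],
        [1, 4, 5], [1, 5, 2],
        [2, 5, 3], [2, 3, 0],
    ])
    return v, f


def _sheared_prism(
    a: np.ndarray, b: np.ndarray, half_y: float, half_z: float
) -> tuple[np.ndarray, np.ndarray]:
    """Prism from a to b with a rectangular y-z cross-section at each station."""
    offs = np.array([
        [0.0, -half_y, -half_z], [0.0, half_y, -half_z],
        [0.0, half_y, half_z], [0.0, -half_y, half_z],
    ])
    v = np.vstack([a + offs, b + offs])
    f = []
    f += [[0, 2, 1], [0, 3, 2]]          # cap at a
    f += [[4, 5, 6], [4, 6, 7]]          # cap at b
    for j in range(4):
        k = (j + 1) % 4
        f += [[j, k, 4 + k], [j, 4 + k, 4 + j]]
    return v, np.asarray(f, dtype=int)


def _notch_pit(
    apex: np.ndarray, half_x: float = 6.0, half_y: float = 4.0, depth: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Inverted pit whose unique lowest vertex is the notch apex."""
    rim = apex + np.array([
        [-half_x, -half_y, depth], [half_x, -half_y, depth],
        [half_x, half_y, depth], [-half_x, half_y, depth],
    ])
    v = np.vstack([apex[None, :], rim])
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 4], [0, 4, 1]])
    return v, f


def _junction_ridge(
    AS: np.ndarray,
    approach: np.ndarray,
    plane_normal: np.ndarray,
    length: float = 30.0,
    dip_deg: float = 20.0,
    n_seg: int = 3,
    flank_w: float = 8.0,
    flank_h: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """V-shaped junction ridge whose crease terminates exactly at AS.

    The crease runs from a start point ``length`` mm away (along the
    in-plane ``approach`` direction, dipping ``dip_deg`` below the
    undersurface plane) up to AS, so the crease is markedly oblique to the
    plane — unlike the plate's own (plane-perpendicular) wall edges.  The
    flank strips give the crease a face-normal dihedral of
    2·atan(flank_h/flank_w) ≈ 41°, inside the detector's crease band but
    away from the plate's 90° box edges.
    """
    m = plane_normal / np.linalg.norm(plane_normal)
    a = np.asarray(approach, dtype=float)
    a = a - (a @ m) * m
    a /= np.linalg.norm(a)
    p0 = AS + length * (math.cos(math.radians(dip_deg)) * a) \
        - length * math.sin(math.radians(dip_deg)) * m
    d = AS - p0
    d /= np.linalg.norm(d)
    w_hat = np.cross(m, d)
    w_hat /= np.linalg.norm(w_hat)
    up = np.cross(d, w_hat)  # ⊥ crease, toward the plane side
    if up @ m < 0:
        up = -up
    f1 = flank_w * w_hat + flank_h * up
    f2 = -flank_w * w_hat + flank_h * up
    ts = np.linspace(0.0, 1.0, n_seg + 1)
    K = p0[None, :] * (1 - ts)[:, None] + AS[None, :] * ts[:, None]
    L = K + f1
    Rr = K + f2
    nv = n_seg + 1
    v = np.vstack([K, L, Rr])
    f = []
    for i in range(n_seg):
        ki, kj = i, i + 1
        li, lj = nv + i, nv + i + 1
        ri, rj = 2 * nv + i, 2 * nv + i + 1
        f += [[ki, kj, li], [li, kj, lj]]
        f += [[kj, ki, ri], [ri, rj, kj]]
    return v, np.asarray(f, dtype=int)


def _plate_mesh(
    p: ScapulaParams, AS: np.ndarray, Rm: np.ndarray
) -> tuple[trimesh.Trimesh, dict]:
    """Acromial plate: extruded (possibly corner-trimmed) box at AS."""
    w = p.acromion_width_mm
    ant = p.acromion_ant_length_mm
    post = p.acromion_post_length_mm
    thick = 0.25 * w
    c_t = p.acromion_corner_trim * w
    c_la = min(c_t, 0.8 * ant)
    c_lp = min(c_t, 0.8 * post)
    if p.acromion_corner_trim == 0.0:
        poly2d = [(0.0, -post), (0.0, ant), (-w, ant), (-w, -post)]
    else:
        poly2d = [
            (0.0, -post), (0.0, ant),
            (-w + c_t, ant), (-w, ant - c_la),
            (-w, -post + c_lp), (-w + c_t, -post),
        ]
    # Extrude the convex plate polygon by hand (fan triangulation).
    npoly = len(poly2d)
    bot = np.array([[t, l, 0.0] for t, l in poly2d])
    top = bot + np.array([0.0, 0.0, thick])
    verts = np.vstack([bot, top])
    faces = []
    for i in range(1, npoly - 1):  # caps
        faces.append([0, i + 1, i])
        faces.append([npoly, npoly + i, npoly + i + 1])
    for i in range(npoly):  # walls
        j = (i + 1) % npoly
        faces.append([i, j, npoly + j])
        faces.append([i, npoly + j, npoly + i])
    B = np.column_stack([Rm @ _EX, Rm @ _EY, Rm @ _EZ])
    mesh2d = trimesh.Trimesh(verts @ B.T + AS, np.asarray(faces, dtype=int), process=False)
    under_world = bot @ B.T + AS
    # border patch: along the (possibly shortened) lateral edge t = −w
    bl = np.linspace(-post + c_lp, ant - c_la, 5)
    border_local = np.stack([np.full(5, -w), bl, np.zeros(5)], axis=1)
    border_world = border_local @ np.column_stack(
        [Rm @ _EX, Rm @ _EY, Rm @ _EZ]
    ).T + AS
    ant_area = 1.0 - (c_t * c_la / 2.0) / (w * ant)
    post_area = 1.0 - (c_t * c_lp / 2.0) / (w * post)
    info = {
        "under_corners": under_world,
        "border_patch": border_world,
        "ant_area": ant_area,
        "post_area": post_area,
        "thick": thick,
    }
    return mesh2d, info


def _expected_record(
    p: ScapulaParams,
    gle: dict,
    plate_Rm: np.ndarray,
    plate_info: dict,
    d_spine: np.ndarray,
) -> MorphometricRecord:
    s = p.perimeter_mm
    llap_dir = plate_Rm @ _EY
    tlap_dir = plate_Rm @ _EX
    O = np.zeros(3)
    apaa = projected_angle(llap_dir, _EY, Plane(O, _EZ))
    spaa = projected_angle(llap_dir, _EZ, Plane(O, _EX))
    cpaa = projected_angle(tlap_dir, _EX, Plane(O, _EY))
    cpssa, spssa, apssa = spine_angles_from_direction(d_spine)
    csa = csa_from_points(
        gle["rim_inferior"], gle["rim_superior"],
        plate_info["under_corners"], p.gv_deg,
    )
    sg = np.asarray(p.sg_offset_mm, dtype=float)
    return MorphometricRecord(
        csa_deg=csa,
        gi_deg=p.gi_deg,
        gv_deg=p.gv_deg,
        acr_box_width_wt=p.acromion_width_mm / s,
        ant_acr_box_length_wt=p.acromion_ant_length_mm / s,
        post_acr_box_length_wt=p.acromion_post_length_mm / s,
        ant_acr_box_area=plate_info["ant_area"],
        post_acr_box_area=plate_info["post_area"],
        cpaa_deg=cpaa, spaa_deg=spaa, apaa_deg=apaa,
        spinal_length_wt=p.spine_length_mm / s,
        cpssa_deg=cpssa, spssa_deg=spssa, apssa_deg=apssa,
        sg_dist_x_wt=abs(sg[0]) / s,
        sg_dist_y_wt=abs(sg[1]) / s,
        sg_dist_z_wt=abs(sg[2]) / s,
    )


def generate_scapula(params: ScapulaParams) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Build a synthetic scapula mesh plus its analytic ground truth.

    Raises :class:`InfeasibleParamsError` for parameter combinations whose
    geometry cannot support the downstream measurement procedures (plate
    intersecting the glenoid, notch outside its detectable corridor, ...).
    """
    p = params
    bs = p.body_scale_mm
    C = np.zeros(3)
    M = _EX * bs
    I = _I_SHAPE * bs
    R = p.glenoid_radius_mm
    SG = np.asarray(p.sg_offset_mm, dtype=float)

    # Feasibility: the SG detection corridor and the notch pit.
    if R + 5.0 >= 0.35 * bs:
        raise InfeasibleParamsError("glenoid radius too large for the body scale")
    if not (0.38 * bs < SG[0] < 0.9 * bs):
        raise InfeasibleParamsError("SG x-offset outside the detectable corridor")
    if SG[2] < 9.5:
        raise InfeasibleParamsError("SG sits too low for the notch construction")

    d_spine = _spine_direction(p)
    AS = M + p.spine_length_mm * d_spine
    plate_Rm = _plate_rotation(p)
    plate, plate_info = _plate_mesh(p, AS, plate_Rm)
    # Plate must stay clear of the glenoid sphere.
    if float(np.min(np.linalg.norm(plate.vertices - C, axis=1))) <= R + 1.0:
        raise InfeasibleParamsError("acromial plate would intersect the glenoid")
    if np.linalg.norm(AS - C) <= R + 2.0:
        raise InfeasibleParamsError("AS point would fall inside the glenoid")

    gv_verts, gv_faces, gle = _glenoid_cap(p)
    bl_verts, bl_faces = _blade(p)
    spine_end = M + 1.35 * (SG - M)
    sp_verts, sp_faces = _sheared_prism(M, spine_end, half_y=4.0, half_z=5.0)
    apex = np.array([SG[0], SG[1], 3.0])
    if SG[2] - 5.0 <= apex[2] + 1.5:
        raise InfeasibleParamsError("spine underside would swallow the notch pit")
    px_verts, px_faces = _notch_pit(apex)
    # The ridge approaches AS along the plate's medial transverse direction,
    # keeping it out of the acromial box footprint.  Its mediolateral extent
    # must also stay clear of the SG detection corridor (the cross-section
    # column at the notch apex), so the ridge length adapts and parameter
    # combinations that leave no room are rejected.
    m_hat = plate_Rm @ _EZ
    rg_verts = rg_faces = None
    for ridge_len in (30.0, 24.0, 18.0, 14.0):
        v_r, f_r = _junction_ridge(
            AS, approach=plate_Rm @ _EX, plane_normal=m_hat, length=ridge_len
        )
        x_lo, x_hi = v_r[:, 0].min() - 3.0, v_r[:, 0].max() + 3.0
        if x_hi < SG[0] - 8.0 or x_lo > SG[0] + 8.0:
            rg_verts, rg_faces = v_r, f_r
            break
    if rg_verts is None:
        raise InfeasibleParamsError(
            "junction ridge cannot avoid the spinoglenoid detection corridor"
        )

    # No other structure may encroach on the acromial box from below: the
    # box construction reads the undersurface as the inferior border of the
    # acromion, so foreign geometry grazing the plate would corrupt it.
    w = p.acromion_width_mm
    t_hat, l_hat = plate_Rm @ _EX, plate_Rm @ _EY
    for v in (gv_verts, bl_verts, sp_verts, px_verts):
        rel = v - AS
        h = rel @ m_hat
        t = rel @ t_hat
        ll = rel @ l_hat
        inside = (
            (t > -w - 4.0) & (t < 6.0)
            & (ll > -p.acromion_post_length_mm - 6.0)
            & (ll < p.acromion_ant_length_mm + 6.0)
        )
        if np.any(inside & (h > -3.0)):
            raise InfeasibleParamsError(
                "scapular body encroaches on the acromial box undersurface"
            )

    parts = [
        trimesh.Trimesh(v, f, process=False)
        for v, f in [
            (gv_verts, gv_faces), (bl_verts, bl_faces),
            (sp_verts, sp_faces), (px_verts, px_faces), (rg_verts, rg_faces),
        ]
    ] + [plate]
    mesh = trimesh.util.concatenate(parts)

    lm = LandmarkSet(
        C=C, M=M, I=I, AS=AS, SG=SG,
        glenoid_rim=gle["rim"],
        rim_superior=gle["rim_superior"],
        rim_inferior=gle["rim_inferior"],
        rim_anterior=gle["rim_anterior"],
        rim_posterior=gle["rim_posterior"],
        glenoid_face_patch=gle["face_patch"],
        acromion_under_patch=plate_info["under_corners"],
        lateral_border_patch=plate_info["border_patch"],
        side=p.side,
        anterior_hint=_EY.copy(),
    )
    record = _expected_record(p, gle, plate_Rm, plate_info, d_spine)

    rng = np.random.default_rng(p.seed)
    if p.noise_mm > 0:
        mesh.vertices += rng.normal(0.0, p.noise_mm, mesh.vertices.shape)
    if p.side == "left":
        mirror = np.diag([1.0, -1.0, 1.0])
        mesh.vertices = mesh.vertices @ mirror
        mesh.faces = mesh.faces[:, ::-1]
        lm = lm.transformed(mirror, np.zeros(3))
    Rw = Rotation.random(rng=rng).as_matrix()
    tw = rng.uniform(-80.0, 80.0, 3)
    mesh.vertices = mesh.vertices @ Rw.T + tw
    lm = lm.transformed(Rw, tw)

    return mesh, GroundTruth(params=p, landmarks=lm, expected_record=record)


def sample_scapula_params(
    rng: np.random.Generator,
    side: str | None = None,
    noise_mm: float = 0.0,
    max_tries: int = 200,
) -> ScapulaParams:
    """Draw feasible scapula parameters within ±2 SD of the printed cohort.

    Angles and weighted lengths are drawn uniformly inside mean ± 2 SD of
    the study's descriptive statistics (on this package's angle
    conventions where they differ; see the methods note), with infeasible
    geometric combinations rejected and redrawn.
    """
    S = _DEFAULT_S
    for _ in range(max_tries):
        s = side if side is not None else ("right", "left")[int(rng.integers(2))]
        try:
            p = ScapulaParams(
                side=s,
                gi_deg=rng.uniform(7.14 - 8.2, 7.14 + 8.2),
                gv_deg=rng.uniform(-12.75, 3.25),
                cpaa_deg=rng.uniform(7.16 - 30.84, 7.16 + 30.84),
                spaa_deg=rng.uniform(42.4, 80.0),
                apaa_deg=rng.uniform(5.3, 44.5),
                cpssa_deg=rng.uniform(26.1, 49.8),
                spssa_deg=rng.uniform(-8.7, 28.7),
                apssa_deg=rng.uniform(-92.5, -63.5),
                acromion_width_mm=rng.uniform(0.06, 0.22) * S,
                acromion_ant_length_mm=rng.uniform(0.22, 0.38) * S,
                acromion_post_length_mm=rng.uniform(0.08, 0.16) * S,
                acromion_corner_trim=rng.uniform(0.1, 0.6),
                spine_length_mm=rng.uniform(0.21, 0.37) * S,
                sg_offset_mm=(
                    rng.uniform(0.13, 0.21) * S,
                    -rng.uniform(0.05, 0.09) * S,
                    rng.uniform(0.035, 0.11) * S,
                ),
                noise_mm=noise_mm,
                seed=int(rng.integers(2**31)),
            )
            generate_scapula(p)
            return p
        except InfeasibleParamsError:
            continue
    raise RuntimeError("could not draw feasible scapula parameters")


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass(frozen=True)
class CohortTruth:
    active_set: tuple[int, ...]
    coefficients: tuple[float, ...]
    intercept: float
    noise_sd: float


@dataclass(frozen=True)
class CohortSimSpec:
    """Simulation design for a predictor table with a known CSA model.

    ``active_set`` holds 0-based column indices of the truly predictive
    variables; ``collinear_groups`` is a sequence of (indices, rho) pairs
    generated with pairwise correlation rho.  When ``n_predictors`` is 17
    the columns are named and scaled like the printed descriptive table;
    otherwise they are standard-normal x1..xp.
    """

    n_subjects: int
    n_predictors: int = 17
    active_set: tuple[int, ...] = (0, 9)
    coefficients: tuple[float, ...] = (0.6, -0.2)
    intercept: float | None = None
    noise_sd: float = 2.0
    collinear_groups: tuple[tuple[tuple[int, ...], float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if len(self.active_set) != len(self.coefficients):
            raise ValueError("active_set and coefficients must have equal length")
        if not set(self.active_set) <= set(range(self.n_predictors)):
            raise ValueError("active_set indices out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for idx, rho in self.collinear_groups:
            if not 0.0 <= rho < 1.0:
                raise ValueError("collinearity rho must lie in [0, 1)")
            if not set(idx) <= set(range(self.n_predictors)):
                raise ValueError("collinear group indices out of range")


def cohort_column_names(n_predictors: int) -> list[str]:
    if n_predictors == 17:
        return list(RECORD_COLUMNS.values())
    return [f"x{i + 1}" for i in range(n_predictors)]


def generate_cohort_table(spec: CohortSimSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a cohort table of predictors + CSA from the known linear model."""
    p = spec.n_predictors
    names = cohort_column_names(p)
    corr = np.eye(p)
    for idx, rho in spec.collinear_groups:
        idx = list(idx)
        for a in idx:
            for b in idx:
                if a != b:
                    corr[a, b] = rho
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation structure for the cohort") from exc
    if p == 17:
        means = np.array([COHORT_MEANS[c] for c in names])
        sds = np.array([COHORT_SDS[c] for c in names])
    else:
        means = np.zeros(p)
        sds = np.ones(p)
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n_subjects, p))
    X = (Z @ L.T) * sds + means
    coefs = np.asarray(spec.coefficients, dtype=float)
    active = list(spec.active_set)
    if spec.intercept is None:
        intercept = 32.8 - float(means[active] @ coefs)
    else:
        intercept = float(spec.intercept)
    y = intercept + X[:, active] @ coefs
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, spec.n_subjects)
    df = pd.DataFrame(X, columns=names)
    df[OUTCOME_COLUMN] = y
    truth = CohortTruth(
        active_set=tuple(spec.active_set),
        coefficients=tuple(float(c) for c in coefs),
        intercept=intercept,
        noise_sd=spec.noise_sd,
    )
    return df, truth


# ---------------------------------------------------------------------------
# Screening logs


@dataclass(frozen=True)
class ScreeningRecord:
    """One scan in the screening log."""

    scan_id: str
    slice_thickness_mm: float
    gross_deformity: bool
    artefact: bool
    complete_scapula: bool

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")


def generate_screening_log(
    counts: tuple[int, int, int, int],
    n_total: int,
    seed: int | None = None,
) -> list[ScreeningRecord]:
    """Screening log with the requested per-criterion exclusion counts.

    ``counts`` follows the criterion order (thick slices, gross deformity,
    artefact, incomplete scapula); each excluded record violates exactly one
    criterion and the remainder are clean.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ValueError("exclusion counts must be non-negative")
    if sum(counts) > n_total:
        raise ValueError("sum of exclusion counts exceeds n_total")
    records: list[ScreeningRecord] = []

    def make(i, thickness=0.625, deformity=False, artefact=False, complete=True):
        return ScreeningRecord(
            scan_id=f"scan_{i:04d}",
            slice_thickness_mm=thickness,
            gross_deformity=deformity,
            artefact=artefact,
            complete_scapula=complete,
        )

    i = 0
    for _ in range(counts[0]):
        records.append(make(i, thickness=1.5)); i += 1
    for _ in range(counts[1]):
        records.append(make(i, deformity=True)); i += 1
    for _ in range(counts[2]):
        records.append(make(i, artefact=True)); i += 1
    for _ in range(counts[3]):
        records.append(make(i, complete=False)); i += 1
    while i < n_total:
        records.append(make(i)); i += 1
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_total)
        records = [records[j] for j in order]
    return records
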