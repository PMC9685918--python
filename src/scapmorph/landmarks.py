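"""Landmark containers and the constructed acromial-box geometry.

Holds the named scapular landmarks (C, M, I, AS, SG, glenoid rim) plus the
annotation "patches" (glenoid articular face, acromial undersurface, lateral
acromial border) that drive the acromial-box construction, and the operations
that locate the acromiospinal (AS) and spinoglenoid (SG) points on synthetic
meshes.  Automatic detection is deliberately scoped to generator-style
meshes; clinical meshes are expected to come with annotations, which are
validated and passed through.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .geometry import (
    Axis3D,
    DegenerateInputError,
    GeometryError,
    Plane,
    ScapularFrame,
    fit_plane,
)

__all__ = [
    "LandmarkError",
    "LandmarkSet",
    "AcromialBox",
    "locate_as_point",
    "locate_sg_point",
    "build_acromial_box",
    "derive_acromial_axes",
]


class LandmarkError(GeometryError):
    """A landmark could not be located or failed validation."""


def _arr(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class LandmarkSet:
    """Named anatomical points and annotation patches, in mesh coordinates (mm).

    ``glenoid_rim`` is an ordered ring of rim points; the four named rim
    points (superior/inferior/anterior/posterior-most) are stored explicitly
    because the glenoid inclination/version measurements need them.
    """

    C: np.ndarray
    M: np.ndarray
    I: np.ndarray
    AS: np.ndarray | None = None
    SG: np.ndarray | None = None
    glenoid_rim: np.ndarray | None = None
    rim_superior: np.ndarray | None = None
    rim_inferior: np.ndarray | None = None
    rim_anterior: np.ndarray | None = None
    rim_posterior: np.ndarray | None = None
    glenoid_face_patch: np.ndarray | None = None
    acromion_under_patch: np.ndarray | None = None
    lateral_border_patch: np.ndarray | None = None
    side: str = "right"
    anterior_hint: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in (
            "C", "M", "I", "AS", "SG", "glenoid_rim",
            "rim_superior", "rim_inferior", "rim_anterior", "rim_posterior",
            "glenoid_face_patch", "acromion_under_patch",
            "lateral_border_patch", "anterior_hint",
        ):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, _arr(v))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply a rigid transform p -> R p + t to every stored coordinate."""
        R = _arr(rotation)
        t = _arr(translation)

        def tx(v):
            if v is None:
                return None
            return _arr(v) @ R.T + t

        kw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "side":
                kw[f.name] = v
            elif f.name == "anterior_hint":
                kw[f.name] = None if v is None else _arr(v) @ R.T
            else:
                kw[f.name] = tx(v)
        return LandmarkSet(**kw)

    def to_json_dict(self) -> dict:
        def ser(v):
            return None if v is None else np.asarray(v).tolist()

        d = {
            "C": ser(self.C),
            "M": ser(self.M),
            "I": ser(self.I),
            "AS": ser(self.AS),
            "SG": ser(self.SG),
            "patches": {
                "glenoid_face": ser(self.glenoid_face_patch),
                "acromion_under": ser(self.acromion_under_patch),
                "lateral_border": ser(self.lateral_border_patch),
            },
            "units": "mm",
            "side": self.side,
            "glenoid_rim": ser(self.glenoid_rim),
            "rim_points": {
                "superior": ser(self.rim_superior),
                "inferior": ser(self.rim_inferior),
                "anterior": ser(self.rim_anterior),
                "posterior": ser(self.rim_posterior),
            },
            "anterior_hint": ser(self.anterior_hint),
        }
        return d

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def from_json_dict(cls, d: dict) -> "LandmarkSet":
        patches = d.get("patches") or {}
        rim_pts = d.get("rim_points") or {}
        return cls(
            C=d["C"], M=d["M"], I=d["I"],
            AS=d.get("AS"), SG=d.get("SG"),
            glenoid_rim=d.get("glenoid_rim"),
            rim_superior=rim_pts.get("superior"),
            rim_inferior=rim_pts.get("inferior"),
            rim_anterior=rim_pts.get("anterior"),
            rim_posterior=rim_pts.get("posterior"),
            glenoid_face_patch=patches.get("glenoid_face"),
            acromion_under_patch=patches.get("acromion_under"),
            lateral_border_patch=patches.get("lateral_border"),
            side=d.get("side", "right"),
            anterior_hint=d.get("anterior_hint"),
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "LandmarkSet":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


@dataclass
class AcromialBox:
    """The five planes bounding/dividing the lateral acromion plus metrics.

    ``lateral_plane`` runs along the best-fit lateral acromial border,
    ``mid_plane`` is its parallel translate through AS; ``anterior_plane``
    and ``posterior_plane`` are orthogonal to them at the acromial extremes,
    and ``as_plane`` (parallel to them, through AS) splits the box into the
    anterior and posterior sub-boxes.  Normals: ``lateral_plane.normal``
    points medially (toward AS) and ``as_plane.normal`` anteriorly.
    """

    lateral_plane: Plane
    mid_plane: Plane
    anterior_plane: Plane
    posterior_plane: Plane
    as_plane: Plane
    under_plane: Plane
    width_mm: float
    ant_length_mm: float
    post_length_mm: float
    llap_axis: Axis3D | None = None
    tlap_axis: Axis3D | None = None

    def __post_init__(self) -> None:
        for a, b in (
            (self.lateral_plane, self.mid_plane),
            (self.anterior_plane, self.posterior_plane),
            (self.anterior_plane, self.as_plane),
        ):
            if abs(abs(float(a.normal @ b.normal)) - 1.0) > 1e-8:
                raise GeometryError("acromial box planes are not parallel as required")
        total = self.ant_length_mm + self.post_length_mm
        span = abs(float(self.anterior_plane.signed_distance(self.posterior_plane.point)))
        if abs(total - span) > 1e-6 * max(1.0, span):
            raise GeometryError("anterior + posterior lengths do not add to the box span")

    @property
    def longitudinal_dir(self) -> np.ndarray:
        """Unit vector along the box's long axis, oriented anteriorly."""
        return self.as_plane.normal

    @property
    def transverse_dir(self) -> np.ndarray:
        """Unit vector across the box, oriented from lateral to medial."""
        return self.lateral_plane.normal


def locate_as_point(
    mesh: trimesh.Trimesh,
    frame: ScapularFrame,
    under_plane: Plane,
    annotation: np.ndarray | None = None,
    crease_band_deg: tuple[float, float] = (25.0, 65.0),
    plane_tol_mm: float = 2.0,
    region_patch: np.ndarray | None = None,
) -> np.ndarray:
    """Locate the acromiospinal (AS) point.

    The AS point terminates the v-shaped spine/acromion junction ridge where
    it meets the acromial undersurface.  Detection finds mesh edges whose
    dihedral (face-normal) angle lies inside ``crease_band_deg`` — the
    junction ridge, by construction of the synthetic meshes — and returns
    the crease vertex closest to the undersurface plane.  When an
    ``annotation`` is supplied it is validated to lie within 2 mm of the
    detected ridge and passed through unchanged.
    """
    angles = np.degrees(mesh.face_adjacency_angles)
    lo, hi = crease_band_deg
    sel = (angles > lo) & (angles < hi)
    if np.any(sel):
        # Drop crease edges running (near-)perpendicular to the undersurface
        # plane: those are wall edges of the plate, not the junction ridge,
        # which approaches the undersurface obliquely.
        edges = mesh.face_adjacency_edges[sel]
        ev = mesh.vertices[edges]
        edir = ev[:, 1] - ev[:, 0]
        edir /= np.linalg.norm(edir, axis=1, keepdims=True)
        sel_e = np.abs(edir @ under_plane.normal) < 0.8
        edges = edges[sel_e]
    else:
        edges = np.empty((0, 2), dtype=int)
    if len(edges) == 0:
        raise LandmarkError(
            "no junction ridge detected on the mesh; supply a manual AS annotation"
        )
    edge_vids = np.unique(edges)
    crease_pts = mesh.vertices[edge_vids]
    if region_patch is not None:
        # Keep only crease vertices whose in-plane footprint lies within the
        # undersurface patch (plus margin): the ridge terminus does, far-away
        # crease structure does not.
        patch = np.atleast_2d(_arr(region_patch))
        e1, e2 = under_plane.basis()
        B = np.stack([e1, e2], axis=1)
        pp = (patch - under_plane.point) @ B
        cc = (crease_pts - under_plane.point) @ B
        lo, hi = pp.min(axis=0) - 8.0, pp.max(axis=0) + 8.0
        near = np.all((cc > lo) & (cc < hi), axis=1)
        if not np.any(near):
            raise LandmarkError(
                "no junction ridge detected near the acromion; "
                "supply a manual AS annotation"
            )
        crease_pts = crease_pts[near]

    if annotation is not None:
        annotation = _arr(annotation)
        d = float(np.min(np.linalg.norm(crease_pts - annotation, axis=1)))
        if d > plane_tol_mm:
            raise LandmarkError(
                f"AS annotation lies {d:.1f} mm from the detected junction ridge "
                f"(limit {plane_tol_mm} mm)"
            )
        return annotation

    dist = np.abs(under_plane.signed_distance(crease_pts))
    i = int(np.argmin(dist))
    if dist[i] > plane_tol_mm:
        raise LandmarkError(
            "junction ridge does not reach the acromial undersurface; "
            "supply a manual AS annotation"
        )
    return crease_pts[i].copy()


def locate_sg_point(
    mesh: trimesh.Trimesh,
    frame: ScapularFrame,
    landmarks: LandmarkSet | None = None,
    annotation: np.ndarray | None = None,
    column_halfwidth_mm: float = 5.0,
) -> np.ndarray:
    """Locate the spinoglenoid (SG) point.

    The notch apex is the deepest (most inferior) point of the spinoglenoid
    notch between the glenoid and the spine; the SG point is the apex moved
    along ẑ to the mid-height of the spine cross-section at the apex's
    mediolateral station.  The search corridor excludes the glenoid (x below
    0.35·CM) and the blade (z below 1 mm in frame coordinates).

    With an ``annotation`` the point is passed through unchanged.
    """
    if annotation is not None:
        return _arr(annotation)
    pts = frame.to_frame(mesh.vertices)
    if landmarks is not None:
        cm = float(np.linalg.norm(_arr(landmarks.M) - _arr(landmarks.C)))
    else:
        cm = float(np.percentile(pts[:, 0], 99.5))
    x_cut = 0.35 * cm
    cand = pts[(pts[:, 0] > x_cut) & (pts[:, 2] > 1.0)]
    if len(cand) == 0:
        raise LandmarkError("spinoglenoid notch not found (empty search corridor)")
    apex = cand[int(np.argmin(cand[:, 2]))]

    # Spine mid-height: z-extent of the spine cross-section at the apex's
    # mediolateral station, taken from an exact plane-mesh section.
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=frame.x_hat, plane_origin=frame.to_world(apex)
    )
    if len(segs) == 0:
        raise LandmarkError("no spine cross-section above the notch apex")
    sec = frame.to_frame(np.asarray(segs, dtype=float).reshape(-1, 3))
    col = sec[
        (np.abs(sec[:, 1] - apex[1]) < 1.5 * column_halfwidth_mm)
        & (sec[:, 2] > apex[2] + 3.0)
    ]
    if len(col) == 0:
        raise LandmarkError("no spine cross-section above the notch apex")
    # The spine is the lowest contiguous band of the column; structures
    # higher up (the acromion) are separated by a z gap wider than the
    # spine cross-section itself.
    zs = np.sort(col[:, 2])
    gaps = np.where(np.diff(zs) > 12.0)[0]
    z_top = zs[gaps[0]] if len(gaps) else zs[-1]
    z_mid = 0.5 * (float(zs[0]) + float(z_top))
    sg_frame = np.array([apex[0], apex[1], z_mid])
    return frame.to_world(sg_frame)


def detect_missing_landmarks(
    mesh: trimesh.Trimesh,
    frame: ScapularFrame,
    landmarks: LandmarkSet,
) -> LandmarkSet:
    """Fill in AS and/or SG by automatic detection when absent.

    The AS search region is anchored on the acromial undersurface patch;
    annotated landmarks are left untouched.
    """
    lm = dataclasses.replace(landmarks)
    if lm.AS is None:
        if lm.acromion_under_patch is None:
            raise LandmarkError("cannot detect AS without the undersurface patch")
        under = fit_plane(lm.acromion_under_patch, orient=frame.z_hat)
        lm.AS = locate_as_point(
            mesh, frame, under, region_patch=lm.acromion_under_patch
        )
    if lm.SG is None:
        lm.SG = locate_sg_point(mesh, frame, landmarks=lm)
    return lm


def build_acromial_box(
    mesh: trimesh.Trimesh,
    frame: ScapularFrame,
    AS: np.ndarray,
    lateral_border_patch: np.ndarray,
    acromion_under_patch: np.ndarray,
    slab_factor: float = 0.5,
) -> AcromialBox:
    """Construct the acromial box from the undersurface and border patches.

    The undersurface viewing plane is the total-least-squares plane of
    ``acromion_under_patch``; the lateral border plane contains the best-fit
    border line and the undersurface normal; the mid plane is its parallel
    translate through AS.  Anterior/posterior planes sit at the extremes of
    the acromial vertices along the box's longitudinal direction, and the
    AS plane (parallel to them, through AS) must lie between them.
    """
    AS = _arr(AS)
    border = np.atleast_2d(_arr(lateral_border_patch))
    under = np.atleast_2d(_arr(acromion_under_patch))
    if len(border) < 2:
        raise DegenerateInputError("lateral border patch needs at least 2 points")
    under_plane = fit_plane(under, orient=frame.z_hat)

    # Border line direction within the undersurface plane.
    n_u = under_plane.normal
    proj = border - np.outer(under_plane.signed_distance(border), n_u)
    centred = proj - proj.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateInputError("lateral border points are coincident")
    l_dir = vt[0]
    if float(l_dir @ frame.y_hat) < 0:  # orient anteriorly
        l_dir = -l_dir
    n_lat = np.cross(l_dir, n_u)
    n_lat /= np.linalg.norm(n_lat)
    lateral_plane = Plane(proj.mean(axis=0), n_lat)
    if float(lateral_plane.signed_distance(AS)) < 0:  # normal points medially
        lateral_plane = Plane(lateral_plane.point, -lateral_plane.normal)
    width = float(abs(lateral_plane.signed_distance(AS)))
    if width < 1e-6:
        raise GeometryError("AS point lies on the lateral border plane; zero-width box")
    mid_plane = Plane(AS, lateral_plane.normal)

    # Acromial vertex slab: near the undersurface, between the two planes.
    h = under_plane.signed_distance(mesh.vertices)
    t = mid_plane.signed_distance(mesh.vertices)  # 0 at mid plane, -width lateral
    slab = (
        (h > -2.0)
        & (h < slab_factor * max(width, 10.0))
        & (t > -width - 2.0)
        & (t < 2.0)
    )
    acr = mesh.vertices[slab]
    if len(acr) == 0:
        raise GeometryError("no acromial vertices found near the undersurface plane")
    l_coord = (acr - AS) @ l_dir
    l_max, l_min = float(l_coord.max()), float(l_coord.min())
    if not (l_min < 0.0 < l_max):
        raise GeometryError("AS point lies outside the anterior-posterior acromial span")
    anterior_plane = Plane(AS + l_max * l_dir, l_dir)
    posterior_plane = Plane(AS + l_min * l_dir, l_dir)
    as_plane = Plane(AS, l_dir)
    return AcromialBox(
        lateral_plane=lateral_plane,
        mid_plane=mid_plane,
        anterior_plane=anterior_plane,
        posterior_plane=posterior_plane,
        as_plane=as_plane,
        under_plane=under_plane,
        width_mm=width,
        ant_length_mm=l_max,
        post_length_mm=-l_min,
    )


def _section_points(mesh: trimesh.Trimesh, plane: Plane) -> np.ndarray:
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.point
    )
    if len(segs) == 0:
        return np.empty((0, 3))
    return np.asarray(segs, dtype=float).reshape(-1, 3)


def derive_acromial_axes(
    box: AcromialBox,
    mesh: trimesh.Trimesh,
    inferior_band_mm: float = 0.75,
) -> tuple[Axis3D, Axis3D]:
    """Derive the longitudinal and transverse lateral acromial axes.

    The LLAP (longitudinal lateral acromial plane) bisects the box
    longitudinally; the TLAP bisects it transversely.  On each plane's
    intersection with the bone, only the inferior border (the section points
    closest to the undersurface) is kept; the LLAP axis joins its
    anterior-most to its posterior-most point, and the TLAP axis joins the
    mutual (LLAP ∩ TLAP) point to the lateral-most point.
    """
    n_med = box.transverse_dir
    l_dir = box.longitudinal_dir
    AS = box.mid_plane.point
    w = box.width_mm
    llap_plane = Plane(AS - 0.5 * w * n_med, n_med)
    l_mid = 0.5 * (box.ant_length_mm - box.post_length_mm)
    tlap_plane = Plane(AS + l_mid * l_dir, l_dir)

    def inferior_border(plane: Plane) -> np.ndarray:
        pts = _section_points(mesh, plane)
        if len(pts) == 0:
            raise GeometryError("plane-mesh intersection is empty")
        h = box.under_plane.signed_distance(pts)
        t = box.mid_plane.signed_distance(pts)
        l = box.as_plane.signed_distance(pts)
        keep = (
            (h > -1.0)
            & (h < 0.5 * max(w, 10.0))
            & (t > -w - 2.0)
            & (t < 2.0)
            & (l > -box.post_length_mm - 2.0)
            & (l < box.ant_length_mm + 2.0)
        )
        pts = pts[keep]
        if len(pts) == 0:
            raise GeometryError("plane-mesh intersection misses the acromial box")
        h = box.under_plane.signed_distance(pts)
        return pts[h < h.min() + inferior_band_mm]

    def on_under_plane(p):
        # pivots live on the inferior border: suppress the residual
        # out-of-plane offset of band points (end-wall section points, noise)
        return p - float(box.under_plane.signed_distance(p)) * box.under_plane.normal

    llap_pts = inferior_border(llap_plane)
    l_coord = box.as_plane.signed_distance(llap_pts)
    p_ant = on_under_plane(llap_pts[int(np.argmax(l_coord))])
    p_post = on_under_plane(llap_pts[int(np.argmin(l_coord))])
    if np.linalg.norm(p_ant - p_post) < 1e-6:
        raise GeometryError("degenerate LLAP inferior border")
    llap_axis = Axis3D.through(p_post, p_ant)

    tlap_pts = inferior_border(tlap_plane)
    d_llap = np.abs(llap_plane.signed_distance(tlap_pts))
    p_mutual = on_under_plane(tlap_pts[int(np.argmin(d_llap))])
    t_coord = box.mid_plane.signed_distance(tlap_pts)
    p_lat = on_under_plane(tlap_pts[int(np.argmin(t_coord))])
    if np.linalg.norm(p_lat - p_mutual) < 1e-6:
        raise GeometryError("degenerate TLAP inferior border")
    tlap_axis = Axis3D.through(p_mutual, p_lat)
    return llap_axis, tlap_axis
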