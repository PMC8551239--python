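"""Craniometric measurements, distance maps and contact-pressure summaries.

Length is glabella-to-opisthocranion, width euryon-to-euryon, and the head
circumference is the perimeter of the outer-table section by the plane
through the glabella, the opisthocranion and the euryon midpoint.  The
cephalic index is 100 x width / length (always recomputed, never stored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MorphometricsReport",
    "DistanceMap",
    "cephalic_index",
    "measure",
    "spring_opening",
    "craniotomy_width",
    "distance_map",
    "pressure_summary",
    "section_perimeter",
]


def cephalic_index(width: float, length: float) -> float:
    """CI = 100 x width / length."""
    if width <= 0 or length <= 0:
        raise ValueError("width and length must be positive")
    return 100.0 * width / length


@dataclass
class MorphometricsReport:
    age: float
    length: float
    width: float
    circumference: float
    icv_volume: float
    spring_openings: dict = field(default_factory=dict)
    spring_forces: dict = field(default_factory=dict)
    contact_pressure: dict = field(default_factory=dict)
    closure: dict = field(default_factory=dict)

    @property
    def cephalic_index(self) -> float:
        return cephalic_index(self.width, self.length)

    def to_dict(self) -> dict:
        d = {
            "age_months": self.age,
            "length_mm": self.length,
            "width_mm": self.width,
            "circumference_mm": self.circumference,
            "cephalic_index": self.cephalic_index,
            "icv_volume_ml": self.icv_volume,
        }
        for k, v in sorted(self.spring_openings.items()):
            d[f"spring_{k:g}mm_opening_mm"] = v
        for k, v in sorted(self.spring_forces.items()):
            d[f"spring_{k:g}mm_force_N"] = v
        for k, v in sorted(self.contact_pressure.items()):
            d[f"pressure_{k}_MPa"] = v
        for k, v in sorted(self.closure.items()):
            d[f"closure_{k}"] = v
        return d


def section_perimeter(points: np.ndarray, faces: np.ndarray, origin, normal) -> float:
    """Perimeter of the section of a triangulated surface by a plane."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    d = (points - np.asarray(origin)) @ normal
    dv = d[faces]
    total = 0.0
    sign = np.sign(dv)
    crossing = np.abs(sign.sum(axis=1)) < 3  # not all on one side
    for tri, dd in zip(faces[crossing], dv[crossing]):
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            da, db = dd[a], dd[b]
            if (da < 0) != (db < 0):
                t = da / (da - db)
                pts.append(points[tri[a]] + t * (points[tri[b]] - points[tri[a]]))
            elif da == 0:
                pts.append(points[tri[a]])
        if len(pts) >= 2:
            total += float(np.linalg.norm(pts[1] - pts[0]))
    return total


def measure(mesh, age: Optional[float] = None) -> MorphometricsReport:
    """Geometric morphometrics of a (possibly deformed) calvarial mesh."""
    for lm in ("glabella", "opisthocranion", "euryon_L", "euryon_R"):
        if lm not in mesh.landmarks:
            raise ValueError(f"landmark {lm!r} missing")
    n = mesh.node_coords
    g = n[mesh.landmarks["glabella"]]
    o = n[mesh.landmarks["opisthocranion"]]
    eL = n[mesh.landmarks["euryon_L"]]
    eR = n[mesh.landmarks["euryon_R"]]
    length = float(np.linalg.norm(g - o))
    width = float(np.linalg.norm(eL - eR))
    # axial measurement plane spanned by the length axis and the euryon axis
    # (through the glabella); the euryon midpoint itself is nearly collinear
    # with glabella/opisthocranion, so it cannot define the plane
    nrm = np.cross(o - g, eR - eL)
    if np.linalg.norm(nrm) < 1e-9:  # degenerate: fall back to the z=0 plane
        nrm = np.array([0.0, 0.0, 1.0])
    # circumference as a tape measure: perimeter of the convex outline of the
    # outer table projected onto the measurement plane
    from scipy.spatial import ConvexHull

    nrm = nrm / np.linalg.norm(nrm)
    e1 = (o - g) / np.linalg.norm(o - g)
    e1 = e1 - (e1 @ nrm) * nrm
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nrm, e1)
    outer_nodes = np.unique(mesh.surfaces["outer_table"])
    rel = n[outer_nodes] - g
    pts2 = np.column_stack([rel @ e1, rel @ e2])
    circ = float(ConvexHull(pts2).area)
    return MorphometricsReport(
        age=age if age is not None else float(mesh.meta.get("age", 0.0)),
        length=length,
        width=width,
        circumference=circ,
        icv_volume=mesh.icv_volume_ml(),
    )


def spring_opening(spring, mesh) -> float:
    """Leg-to-leg distance of a distractor in the current configuration."""
    if spring.removed:
        raise ValueError("spring has been removed; no opening defined")
    cL, cR = spring.leg_points(mesh.node_coords)
    return float(np.linalg.norm(cR - cL))


def craniotomy_width(mesh, n_stations: int = 9) -> float:
    """Mean mediolateral edge-to-edge separation of the craniotomy strip.

    Sampled at stations along the strip: at each station the innermost
    bone-edge nodes left and right of the midline are paired.
    """
    lab = mesh.region_labels
    strip = lab == "craniotomy"
    if not strip.any():
        raise ValueError("mesh has no craniotomy")
    strip_nodes = np.unique(mesh.tets[strip])
    bone_elems = np.isin(
        lab, ["parietal_L", "parietal_R", "frontal_L", "frontal_R", "occipital"]
    )
    bone_nodes = np.unique(mesh.tets[bone_elems])
    edge = np.intersect1d(strip_nodes, bone_nodes)
    pts = mesh.node_coords[edge]
    left, right = pts[pts[:, 0] < 0], pts[pts[:, 0] >= 0]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("craniotomy strip has no bilateral bone edges")
    y0 = max(left[:, 1].min(), right[:, 1].min())
    y1 = min(left[:, 1].max(), right[:, 1].max())
    ys = np.linspace(y0, y1, n_stations)
    widths = []
    for y in ys:
        l = left[np.abs(left[:, 1] - y) < 6.0]
        r = right[np.abs(right[:, 1] - y) < 6.0]
        if len(l) and len(r):
            widths.append(r[:, 0].min() - l[:, 0].max())
    return float(np.mean(widths))


@dataclass
class DistanceMap:
    distances: np.ndarray  # signed mm per subject vertex

    @property
    def mean_abs(self) -> float:
        return float(np.abs(self.distances).mean())

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.distances).max())

    def fraction_within(self, tol: float = 2.0) -> float:
        return float((np.abs(self.distances) <= tol).mean())


def distance_map(subject, reference) -> DistanceMap:
    """Signed nearest-point distances from subject vertices to a reference
    surface; positive where the subject lies outside the reference
    (along the reference outward normal).

    Surfaces are (vertices, faces) pairs with outward-wound faces.
    """
    from .fe_core import _point_triangle_project

    sv, _ = subject
    rv, rf = reference
    sv = np.asarray(sv, float)
    rv = np.asarray(rv, float)
    rf = np.asarray(rf)
    if len(sv) == 0 or len(rf) == 0:
        raise ValueError("empty surface")
    cent = rv[rf].mean(axis=1)
    tree = cKDTree(cent)
    k = min(8, len(rf))
    _, cand = tree.query(sv, k=k)
    cand = np.atleast_2d(cand)
    best = np.full(len(sv), np.inf)
    signed = np.zeros(len(sv))
    for col in range(cand.shape[1]):
        f = rf[cand[:, col]]
        proj, _ = _point_triangle_project(sv, rv[f[:, 0]], rv[f[:, 1]], rv[f[:, 2]])
        vec = sv - proj
        d = np.linalg.norm(vec, axis=1)
        nrm = np.cross(rv[f[:, 1]] - rv[f[:, 0]], rv[f[:, 2]] - rv[f[:, 0]])
        sgn = np.where(np.einsum("ij,ij->i", vec, nrm) >= 0, 1.0, -1.0)
        better = d < best
        best[better] = d[better]
        signed[better] = (sgn * d)[better]
    return DistanceMap(signed)


_DEFAULT_REGIONS = ("anterior", "posterior", "mediolateral_L", "mediolateral_R", "vertex")


def _partition_icv_faces(mesh) -> dict:
    faces = mesh.surfaces["icv_surface"]
    c = mesh.node_coords[faces].mean(axis=1)
    zmax = c[:, 2].max()
    ymax, ymin = c[:, 1].max(), c[:, 1].min()
    out = {}
    vertex = c[:, 2] > 0.55 * zmax
    anterior = ~vertex & (c[:, 1] > 0.35 * ymax)
    posterior = ~vertex & (c[:, 1] < 0.35 * ymin)
    rest = ~(vertex | anterior | posterior)
    out["vertex"] = np.flatnonzero(vertex)
    out["anterior"] = np.flatnonzero(anterior)
    out["posterior"] = np.flatnonzero(posterior)
    out["mediolateral_L"] = np.flatnonzero(rest & (c[:, 0] < 0))
    out["mediolateral_R"] = np.flatnonzero(rest & (c[:, 0] >= 0))
    return out


def pressure_summary(mesh, face_pressures: np.ndarray, partition: Optional[dict] = None) -> dict:
    """Per-region mean/max contact pressure over the ICV surface (MPa)."""
    import warnings

    if partition is None:
        partition = _partition_icv_faces(mesh)
    faces = mesh.surfaces["icv_surface"]
    pts = mesh.node_coords
    areas = 0.5 * np.linalg.norm(
        np.cross(pts[faces[:, 1]] - pts[faces[:, 0]], pts[faces[:, 2]] - pts[faces[:, 0]]),
        axis=1,
    )
    p = np.asarray(face_pressures)
    out = {
        "mean": float(np.average(p, weights=areas)),
        "max": float(p.max(initial=0.0)),
    }
    for name, idx in partition.items():
        if len(idx) == 0:
            warnings.warn(f"empty pressure region {name!r}; omitted", stacklevel=2)
            continue
        out[f"{name}_mean"] = float(np.average(p[idx], weights=areas[idx]))
        out[f"{name}_max"] = float(p[idx].max(initial=0.0))
    return out
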