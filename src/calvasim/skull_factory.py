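"""Deterministic parametric generator of a synthetic infant calvaria.

The calvaria is modelled as a thickened closed shell whose horizontal
cross-sections are superellipses (the exponent is solved so the outer
midplane perimeter matches a target head circumference) and whose vertical
profile is a half-ellipsoid dome closed below by a flattened basal dish.
The enclosed intracranial volume (ICV) is meshed as a separate tetrahedral
ball whose outer surface is geometrically coincident with the inner table,
so the two bodies start in contact but are free to separate or press on one
another through the contact formulation.

Anatomical frame: x mediolateral (+x = right), y anteroposterior
(+y = anterior), z dorsoventral (+z = vertex), origin at the skull centre.
All coordinates in mm.

Vault plates, sutures (coronal, lambdoid, squamosal, metopic), the fused
sagittal suture and the anterior fontanelle are labeled element regions;
virtual surgery relabels a strip of bone/fused suture as ``craniotomy`` and
tags spring anchor node groups for spring-assisted cranioplasty (SAC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .materials import Spring, SpringSet, spring_stiffness

__all__ = ["CalvarialMesh", "SurgeryPlan", "build_calvaria", "apply_surgery", "place_springs"]

REGION_DTYPE = "U20"


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class CalvarialMesh:
    """Labeled tetrahedral mesh of the calvaria plus intracranial volume.

    ``surfaces`` maps tag -> (ntri, 3) node-index triangles; ``inner_table``
    triangles are wound so their normals point into the cranial cavity,
    ``outer_table`` and ``icv_surface`` point outward.  ``node_sets`` holds
    constraint patches and spring anchors; ``landmarks`` are node indices of
    craniometric points on the outer table.
    """

    node_coords: np.ndarray
    tets: np.ndarray
    region_labels: np.ndarray
    surfaces: dict
    node_sets: dict
    landmarks: dict
    meta: dict = field(default_factory=dict)

    # -- geometry helpers ---------------------------------------------------
    def tet_volumes(self) -> np.ndarray:
        x = self.node_coords[self.tets]
        e = x[:, 1:] - x[:, :1]
        return np.linalg.det(e) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.tets].mean(axis=1)

    def element_size(self) -> float:
        return float(self.meta.get("element_size", self._mean_edge()))

    def _mean_edge(self) -> float:
        t = self.tets[:: max(1, len(self.tets) // 2000)]
        x = self.node_coords[t]
        e = np.concatenate(
            [x[:, a] - x[:, b] for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
        )
        return float(np.linalg.norm(e, axis=1).mean())

    def icv_volume_ml(self) -> float:
        return float(self.tet_volumes()[self.region_labels == "icv"].sum() / 1000.0)

    def copy(self) -> "CalvarialMesh":
        return CalvarialMesh(
            self.node_coords.copy(),
            self.tets,
            self.region_labels.copy(),
            self.surfaces,
            {k: v.copy() for k, v in self.node_sets.items()},
            dict(self.landmarks),
            dict(self.meta),
        )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        vols = self.tet_volumes()
        if (vols <= 0).any():
            worst = np.argsort(vols)[:5]
            raise ValueError(f"mesh has non-positive tetrahedra, worst elements {worst.tolist()}")
        if len(self.region_labels) != len(self.tets):
            raise ValueError("one region label per element required")
        for name in ("foramen_magnum_ring", "nasal_ridge_patch"):
            if len(self.node_sets.get(name, ())) == 0:
                raise ValueError(f"node set {name!r} empty")
        if np.intersect1d(
            self.node_sets["foramen_magnum_ring"], self.node_sets["nasal_ridge_patch"]
        ).size:
            raise ValueError("foramen magnum ring and nasal ridge patch overlap")
        outer_nodes = np.unique(self.surfaces["outer_table"])
        for name, idx in self.landmarks.items():
            if idx not in outer_nodes:
                raise ValueError(f"landmark {name!r} not on the outer table")
        # icv forms one connected component
        icv = self.region_labels == "icv"
        if icv.any():
            sub = self.tets[icv]
            nodes, inv = np.unique(sub, return_inverse=True)
            inv = inv.reshape(sub.shape)
            ii = np.concatenate([inv[:, 0], inv[:, 0], inv[:, 0], inv[:, 1], inv[:, 1], inv[:, 2]])
            jj = np.concatenate([inv[:, 1], inv[:, 2], inv[:, 3], inv[:, 2], inv[:, 3], inv[:, 3]])
            g = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(len(nodes),) * 2)
            n_comp, _ = connected_components(g.tocsr(), directed=False)
            if n_comp != 1:
                raise ValueError(f"icv region splits into {n_comp} components")


# ---------------------------------------------------------------------------
# UV sphere primitives
# ---------------------------------------------------------------------------


def uv_sphere(nlat: int, nlon: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit lat/long sphere with exact equator ring and axis-aligned meridians.

    ``nlat`` must be even and ``nlon`` divisible by 4 so that nodes fall
    exactly on the equator and on the +-x / +-y meridians (used for
    landmarks and midline suture lines).
    """
    if nlat % 2 or nlon % 4:
        raise ValueError("nlat must be even and nlon divisible by 4")
    lat = -np.pi / 2 + np.pi * np.arange(1, nlat) / nlat
    lon = 2 * np.pi * np.arange(nlon) / nlon
    ll, bb = np.meshgrid(lon, lat)
    ring = np.stack(
        [np.cos(bb) * np.cos(ll), np.cos(bb) * np.sin(ll), np.sin(bb)], axis=-1
    ).reshape(-1, 3)
    verts = np.vstack([[0.0, 0.0, -1.0], ring, [0.0, 0.0, 1.0]])

    def vid(i, j):  # ring i in 1..nlat-1, lon j (wraps)
        return 1 + (i - 1) * nlon + (j % nlon)

    faces = []
    for j in range(nlon):  # bottom fan
        faces.append((0, vid(1, j + 1), vid(1, j)))
    for i in range(1, nlat - 1):
        for j in range(nlon):
            q = (vid(i, j), vid(i, j + 1), vid(i + 1, j + 1), vid(i + 1, j))
            k = int(np.argmin(q))
            if k in (0, 2):
                faces.append((q[0], q[1], q[2]))
                faces.append((q[0], q[2], q[3]))
            else:
                faces.append((q[0], q[1], q[3]))
                faces.append((q[1], q[2], q[3]))
    top = len(verts) - 1
    for j in range(nlon):  # top fan
        faces.append((top, vid(nlat - 1, j), vid(nlat - 1, j + 1)))
    return verts, np.asarray(faces, dtype=np.int64)


def _superellipse_shape(
    verts: np.ndarray, p: float, base_flatten: float, q: float = 2.0
) -> np.ndarray:
    """Map unit-sphere points to the unit skull shape (degree-1 homogeneous).

    ``p`` shapes the horizontal cross-section (2 = ellipse, larger = boxier,
    solved from the circumference target); ``q`` shapes the vertical profile
    (2 = elliptical dome, larger = flat-topped vault with steep side walls,
    the keel-like coronal section typical of scaphocephaly).
    """
    out = verts.copy()
    r = np.hypot(verts[:, 0], verts[:, 1])
    mask = r > 1e-12
    th = np.arctan2(verts[:, 1], verts[:, 0])
    s = (np.abs(np.cos(th)) ** p + np.abs(np.sin(th)) ** p) ** (-1.0 / p)
    out[mask, 0] *= s[mask]
    out[mask, 1] *= s[mask]
    if q != 2.0:
        # reshape the (horizontal radius, height) profile to a superellipse
        lam = np.arcsin(np.clip(verts[:, 2], -1, 1))
        rr = np.abs(np.cos(lam)) ** (2.0 / q)
        zz = np.sign(verts[:, 2]) * np.abs(np.sin(lam)) ** (2.0 / q)
        grow = np.where(mask, rr / np.where(mask, r, 1.0), 1.0)
        out[:, 0] *= grow
        out[:, 1] *= grow
        out[:, 2] = zz
    neg = out[:, 2] < 0
    out[neg, 2] *= base_flatten
    return out


def superellipse_perimeter(a: float, b: float, p: float, n: int = 4000) -> float:
    t = np.linspace(0, np.pi / 2, n)
    x = a * np.cos(t) ** (2.0 / p)
    y = b * np.sin(t) ** (2.0 / p)
    return 4.0 * float(np.hypot(np.diff(x), np.diff(y)).sum())


def _split_wedges(bot: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split wedges (triangular prisms) into 3 tets each, conforming across
    shared quad faces via the smallest-global-index diagonal rule."""
    w = np.hstack([bot, top])  # (n, 6): a0 a1 a2 b0 b1 b2
    perms = np.array(
        [
            [0, 1, 2, 3, 4, 5],
            [1, 2, 0, 4, 5, 3],
            [2, 0, 1, 5, 3, 4],
            [3, 5, 4, 0, 2, 1],
            [4, 3, 5, 1, 0, 2],
            [5, 4, 3, 2, 1, 0],
        ]
    )
    amin = np.argmin(w, axis=1)
    wr = np.take_along_axis(w, perms[amin], axis=1)
    cond = np.minimum(wr[:, 1], wr[:, 5]) < np.minimum(wr[:, 2], wr[:, 4])
    t_a = np.stack([wr[:, [0, 1, 2, 5]], wr[:, [0, 1, 5, 4]], wr[:, [0, 4, 5, 3]]], axis=1)
    t_b = np.stack([wr[:, [0, 1, 2, 4]], wr[:, [0, 4, 2, 5]], wr[:, [0, 4, 5, 3]]], axis=1)
    tets = np.where(cond[:, None, None], t_a, t_b)
    return tets.reshape(-1, 4)


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = vol < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def _vertex_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]])
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    # orient outward (positive dot with position; shape is star-convex)
    sign = np.sign(np.einsum("ij,ij->i", vn, verts))
    sign[sign == 0] = 1.0
    vn *= sign[:, None]
    return vn / np.linalg.norm(vn, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def build_calvaria(
    length: float = 137.2,
    width: float = 108.1,
    circumference: Optional[float] = 430.6,
    icv_volume_ml: float = 659.9,
    thickness: float = 1.0,
    suture_width: float = 2.0,
    base_flatten: float = 0.4,
    fontanelle_radius: float = 12.0,
    posterior_fontanelle_radius: float = 0.0,
    coronal_y_frac: float = 0.45,
    lambdoid_y_frac: float = -0.78,
    squamosal_z_frac: float = 0.28,
    shell_nlat: int = 18,
    shell_nlon: int = 36,
    shell_layers: int = 1,
    icv_nlat: int = 8,
    icv_nlon: int = 16,
    icv_layer_fractions: Sequence[float] = (0.45, 0.7, 0.88, 1.0),
    superellipse_exponent: Optional[float] = None,
    profile_exponent: float = 2.0,
    base_gap: Optional[tuple] = (-0.8, -0.55),
    jitter: float = 0.0,
    seed: int = 0,
) -> CalvarialMesh:
    """Build the synthetic pre-operative calvaria.

    With default parameters the generated skull measures length/width/
    circumference close to 137.2/108.1/430.6 mm and encloses an ICV of
    659.9 ml (the superellipse exponent and the dome height are solved from
    the circumference and volume targets at build time).  Identical
    parameters and seed reproduce the mesh bit-for-bit.
    """
    if min(length, width, icv_volume_ml) <= 0 or thickness <= 0:
        raise ValueError("dimensions, thickness and target volume must be positive")
    if suture_width <= 0 or suture_width > 20.0:
        raise ValueError("suture band width must lie in (0, 20] mm")
    if not 0 < base_flatten <= 1.0:
        raise ValueError("base_flatten must lie in (0, 1]")
    a_i = width / 2.0 - thickness
    b_i = length / 2.0 - thickness
    if min(a_i, b_i) <= 5 * suture_width:
        raise ValueError("suture band wider than the bone plates it separates")

    n_est = 6 * shell_nlon * (shell_nlat - 1) * shell_layers + 8 * icv_nlon * (icv_nlat - 1) * len(
        tuple(icv_layer_fractions)
    )
    if not 5_000 <= n_est <= 500_000:
        raise ValueError(f"resolution gives ~{n_est} elements, outside the 5k-500k desk range")

    # superellipse exponent from the circumference target (outer offset curve
    # of a convex section has perimeter P_inner + 2*pi*t)
    if superellipse_exponent is not None:
        p = float(superellipse_exponent)
    elif circumference is None:
        p = 2.0
    else:
        target = circumference - 2 * np.pi * thickness

        def f(pp):
            return superellipse_perimeter(a_i, b_i, pp) - target

        if f(2.0) > 0:
            raise ValueError("circumference target below the elliptical perimeter floor")
        if f(12.0) < 0:
            raise ValueError("circumference target unreachable (section would be rectangular)")
        p = float(brentq(f, 2.0, 12.0, xtol=1e-6))

    # --- ICV ball (solve dome height c so the discrete volume is exact) ---
    iv_u, if_u = uv_sphere(icv_nlat, icv_nlon)
    iv_s = _superellipse_shape(iv_u, p, base_flatten, profile_exponent)
    fracs = np.asarray(tuple(icv_layer_fractions), dtype=float)
    if fracs[-1] != 1.0 or np.any(np.diff(fracs) <= 0) or fracs[0] <= 0:
        raise ValueError("icv_layer_fractions must increase and end at 1.0")
    nvi = len(iv_s)
    sheets = [f * iv_s for f in fracs]
    param_nodes = np.vstack(sheets + [[[0.0, 0.0, 0.0]]])
    centre = len(param_nodes) - 1
    icv_tets = [np.column_stack([np.full(len(if_u), centre), if_u[:, 0], if_u[:, 1], if_u[:, 2]])]
    for k in range(len(fracs) - 1):
        icv_tets.append(_split_wedges(if_u + k * nvi, if_u + (k + 1) * nvi))
    icv_tets = np.vstack(icv_tets)
    icv_tets = _fix_orientation(param_nodes, icv_tets)
    x = param_nodes[icv_tets]
    v_unit = float(np.abs(np.linalg.det(x[:, 1:] - x[:, :1])).sum() / 6.0)
    c_i = icv_volume_ml * 1000.0 / (a_i * b_i * v_unit)

    scale = np.array([a_i, b_i, c_i])
    icv_nodes = param_nodes * scale

    # --- shell ---
    sv_u, sf = uv_sphere(shell_nlat, shell_nlon)
    inner = _superellipse_shape(sv_u, p, base_flatten, profile_exponent) * scale
    normals = _vertex_normals(inner, sf)
    nvs = len(inner)
    # the cranial base is substantially thicker than the vault: grade the
    # shell from the nominal vault thickness at/above the rim to 3x at the
    # basal pole (also keeps the flat basal elements well-conditioned)
    t_vertex = thickness * (1.0 + 2.0 * np.clip(-sv_u[:, 2], 0.0, 1.0))
    shell_sheets = [
        inner + (k / shell_layers) * t_vertex[:, None] * normals
        for k in range(shell_layers + 1)
    ]
    shell_nodes = np.vstack(shell_sheets)
    shell_tets = np.vstack(
        [_split_wedges(sf + k * nvs, sf + (k + 1) * nvs) for k in range(shell_layers)]
    )

    # open inferior boundary: drop the annular band of shell between the
    # vault rim and the basilar cap (growth escapes into the cranial fossae
    # the way it does past the open lower edge of a segmented calvaria);
    # the cap survives to carry the foramen magnum constraint
    wbar_face = sv_u[sf, 2].mean(axis=1)
    if base_gap is not None:
        lo, hi = base_gap
        face_keep = ~((wbar_face > lo) & (wbar_face < hi))
    else:
        face_keep = np.ones(len(sf), dtype=bool)
    wedge_keep = np.concatenate([np.repeat(face_keep, 3)] * shell_layers)
    shell_tets = shell_tets[wedge_keep]

    nodes = np.vstack([shell_nodes, icv_nodes])
    icv_off = len(shell_nodes)
    tets = np.vstack([shell_tets, icv_tets + icv_off])
    tets = _fix_orientation(nodes, tets)

    # --- region labels ---
    y_cor = coronal_y_frac * b_i
    y_lam = lambdoid_y_frac * b_i
    z_sq = squamosal_z_frac * c_i
    h = suture_width / 2.0
    face_labels = _label_faces(
        inner, sv_u, sf, y_cor, y_lam, z_sq, h, fontanelle_radius,
        posterior_fontanelle_radius, a_i,
    )
    shell_labels = np.concatenate([np.repeat(face_labels, 3)] * shell_layers)[wedge_keep]
    labels = np.concatenate(
        [shell_labels, np.full(len(icv_tets), "icv", dtype=REGION_DTYPE)]
    ).astype(REGION_DTYPE)

    # --- surfaces ---
    outer_off = shell_layers * nvs
    surfaces = {
        "outer_table": sf[face_keep] + outer_off,
        "inner_table": sf[face_keep][:, ::-1].copy(),  # wound toward the cavity
        "icv_surface": if_u + (len(fracs) - 1) * nvi + icv_off,
    }

    # --- node sets (constraint patches) ---
    w_shell = np.tile(sv_u[:, 2], shell_layers + 1)
    v_shell = np.tile(sv_u[:, 1], shell_layers + 1)
    shell_ids = np.arange(len(shell_nodes))
    foramen = shell_ids[w_shell <= -0.94]
    nasal = shell_ids[(v_shell >= 0.93) & (w_shell > -0.35) & (w_shell <= 0.02)]
    w_icv = np.concatenate([np.tile(iv_u[:, 2], len(fracs)), [0.0]])
    icv_ids = np.arange(len(icv_nodes)) + icv_off
    icv_base = icv_ids[np.concatenate([np.tile(iv_u[:, 2], len(fracs)), [1.0]]) <= -0.9]
    node_sets = {
        "foramen_magnum_ring": foramen,
        "nasal_ridge_patch": nasal,
        "icv_base": icv_base,
    }
    orphans = np.setdiff1d(np.arange(len(nodes)), np.unique(tets))
    if len(orphans):
        node_sets["unused_nodes"] = orphans  # always pinned by the solver

    # --- landmarks (exact parametric positions on the outer table) ---
    i_eq = shell_nlat // 2

    def ring_id(i, j):
        return 1 + (i - 1) * shell_nlon + j

    landmarks = {
        "euryon_R": outer_off + ring_id(i_eq, 0),
        "glabella": outer_off + ring_id(i_eq, shell_nlon // 4),
        "euryon_L": outer_off + ring_id(i_eq, shell_nlon // 2),
        "opisthocranion": outer_off + ring_id(i_eq, 3 * shell_nlon // 4),
    }

    if jitter > 0:
        rng = np.random.default_rng(seed)
        protect = np.zeros(len(nodes), dtype=bool)
        protect[:nvs] = True  # shell inner sheet stays put
        protect[icv_off + (len(fracs) - 1) * nvi : icv_off + len(fracs) * nvi] = True
        disp = rng.normal(0.0, jitter, nodes.shape)
        disp[protect] = 0.0
        nodes = nodes + disp
        tets = _fix_orientation(nodes, tets)

    edge = nodes[sf[:, 0]] - nodes[sf[:, 1]]
    meta = {
        "a_inner": a_i,
        "b_inner": b_i,
        "c_inner": c_i,
        "superellipse_p": p,
        "profile_q": profile_exponent,
        "thickness": thickness,
        "suture_half_width": h,
        "coronal_y": y_cor,
        "lambdoid_y": y_lam,
        "squamosal_z": z_sq,
        "fontanelle_radius": fontanelle_radius,
        "element_size": float(np.linalg.norm(edge, axis=1).mean()),
        "n_shell_nodes": len(shell_nodes),
        "shell_layers": shell_layers,
        "seed": seed,
        "technique": "preoperative",
    }
    mesh = CalvarialMesh(nodes, tets, labels, surfaces, node_sets, landmarks, meta)
    mesh.validate()
    _record_contact_bias(mesh)
    return mesh


def _record_contact_bias(mesh: CalvarialMesh) -> None:
    """Record the as-built ICV-node offsets from the inner table.

    The ICV surface and the inner table triangulate the same smooth interface
    at different resolutions; their apparent node-to-facet gaps are chord
    artefacts, not separation.  The contact solver subtracts these.
    """
    from .fe_core import build_contact_state, ContactSpec

    cs = build_contact_state(mesh, ContactSpec())
    if cs is not None:
        mesh.meta["contact_bias_nodes"] = cs.slave_nodes
        mesh.meta["contact_bias_values"] = cs.gap0.copy()


def _label_faces(inner, unit, faces, y_cor, y_lam, z_sq, h, r_af, r_pf, a_i):
    """Label each shell surface face with its anatomical region."""
    fx = inner[faces]  # (F,3,3) physical corner coords
    cx = fx.mean(axis=1)
    wbar = unit[faces, 2].mean(axis=1)
    x_c, y_c, z_c = cx[:, 0], cx[:, 1], cx[:, 2]

    def band(vals, centre, half):
        lo = vals.min(axis=1) - centre
        hi = vals.max(axis=1) - centre
        near = np.min(np.abs(vals - centre), axis=1) <= half
        return near | ((lo < 0) & (hi > 0))

    xband0 = band(fx[:, :, 0], 0.0, h)
    yband_cor = band(fx[:, :, 1], y_cor, h)
    yband_lam = band(fx[:, :, 1], y_lam, h)
    zband_sq = band(fx[:, :, 2], z_sq, h)

    lab = np.full(len(faces), "", dtype=REGION_DTYPE)
    above = wbar > -0.05
    af = (np.hypot(x_c, y_c - y_cor) <= r_af) & (wbar > 0.15)
    lab[af] = "anterior_fontanelle"
    # optional posterior fontanelle: open membranous lambda region where the
    # sagittal line meets the lambdoid suture
    if r_pf > 0:
        pf = (np.hypot(x_c, y_c - y_lam) <= r_pf) & (wbar > 0.1)
        lab[pf & (lab == "")] = "lambdoid_suture"
    free = lab == ""
    lab[free & above & xband0 & (y_c > y_cor)] = "metopic_suture"
    free = lab == ""
    lab[free & above & xband0 & (y_c <= y_cor) & (y_c >= y_lam)] = "fused_sagittal"
    free = lab == ""
    lab[free & above & yband_cor] = "coronal_suture"
    free = lab == ""
    lab[free & above & yband_lam] = "lambdoid_suture"
    free = lab == ""
    # the squamosal band continues around the full vault perimeter: in the
    # infant the vault plates join the cranial base through patent sutures
    # and synchondroses, so the vault floats on a compliant ring
    lab[free & zband_sq] = "squamosal_suture"
    free = lab == ""
    vbar = unit[faces, 1].mean(axis=1)
    # bony islands of the base: the supraorbital/nasal wedge (anterior, which
    # carries the nasal-ridge constraint) and the basilar occiput around the
    # foramen magnum; the rest of the sub-equatorial shell stays a compliant
    # synchondrosis ring
    nasal_bone = free & (vbar >= 0.86) & (wbar <= -0.05) & (wbar > -0.55)
    side = np.where(x_c < 0, "_L", "_R")
    lab[nasal_bone] = np.char.add("frontal", side[nasal_bone])
    free = lab == ""
    lab[free & (wbar <= -0.8)] = "occipital"
    free = lab == ""
    lab[free & (wbar <= -0.05)] = "basal_plate"
    free = lab == ""
    side = np.where(x_c < 0, "_L", "_R")
    frontal = free & (y_c > y_cor)
    lab[frontal] = np.char.add("frontal", side[frontal])
    free = lab == ""
    occ = free & (y_c < y_lam)
    lab[occ] = "occipital"
    free = lab == ""
    par = free & (z_c >= z_sq)
    lab[par] = np.char.add("parietal", side[par])
    free = lab == ""
    lab[free] = np.char.add("temporal", side[free])
    return lab


# ---------------------------------------------------------------------------
# Virtual surgery
# ---------------------------------------------------------------------------

_TECHNIQUES = {"SAC2", "SAC3", "MSC"}


@dataclass
class SurgeryPlan:
    """Craniotomy geometry and spring layout for one corrective technique.

    SAC: 1 mm midline strip from the anterior fontanelle to the lambdoid
    suture with springs 40/(55)/75 mm behind the coronal suture.  MSC: 50 mm
    vertex strip from coronal to lambdoid, no springs.
    """

    technique: str
    craniotomy_width: float = None  # type: ignore[assignment]
    spring_positions: tuple = None  # type: ignore[assignment]
    burr_hole_spacing: float = 15.0
    extent: Optional[tuple] = None  # (y_posterior, y_anterior) override, mm

    def __post_init__(self):
        if self.technique not in _TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.craniotomy_width is None:
            self.craniotomy_width = 50.0 if self.technique == "MSC" else 1.0
        if self.spring_positions is None:
            self.spring_positions = {
                "SAC2": (40.0, 75.0),
                "SAC3": (40.0, 55.0, 75.0),
                "MSC": (),
            }[self.technique]
        else:
            self.spring_positions = tuple(self.spring_positions)


def apply_surgery(mesh: CalvarialMesh, plan: SurgeryPlan) -> CalvarialMesh:
    """Relabel the craniotomy strip and tag spring anchor node groups."""
    out = mesh.copy()
    meta = out.meta
    h_sut = meta["suture_half_width"]
    y_cor, y_lam = meta["coronal_y"], meta["lambdoid_y"]
    if plan.extent is not None:
        y0, y1 = plan.extent
    elif plan.technique == "MSC":
        y0, y1 = y_lam + h_sut, y_cor - h_sut
    else:
        y0, y1 = y_lam + h_sut, y_cor - meta["fontanelle_radius"]
    if y1 <= y0:
        warnings.warn("zero-length craniotomy extent: mesh unchanged", stacklevel=2)
        return out

    labels = out.region_labels
    allowed = np.isin(labels, ["parietal_L", "parietal_R", "fused_sagittal"])
    nodes = out.node_coords
    xs = nodes[out.tets, 0]
    cent = out.element_centroids()
    half = plan.craniotomy_width / 2.0
    if plan.craniotomy_width <= 3.0 * out.element_size():
        in_x = (np.min(np.abs(xs), axis=1) <= half) | (
            (xs.min(axis=1) < 0) & (xs.max(axis=1) > 0)
        )
    else:
        in_x = np.abs(cent[:, 0]) <= half
    in_y = (cent[:, 1] >= y0) & (cent[:, 1] <= y1)
    on_top = cent[:, 2] > 0.05 * meta["c_inner"]
    strip = allowed & in_x & in_y & on_top
    if not strip.any():
        raise ValueError("craniotomy strip misses the calvarial shell")
    out.region_labels = labels.copy()
    out.region_labels[strip] = "craniotomy"

    meta["craniotomy_y_range"] = (float(y0), float(y1))
    meta["craniotomy_width"] = float(plan.craniotomy_width)
    meta["technique"] = plan.technique
    meta["spring_positions_mm"] = tuple(plan.spring_positions)

    if plan.technique != "MSC":
        _tag_anchors(out, plan, y0, y1)
    out.validate()
    return out


def _containing_surface_triangle(mesh: CalvarialMesh, x_t: float, y_s: float):
    """Outer-table triangle containing (x_t, y_s) in plan view, with its
    barycentric coordinates; falls back to the nearest triangle."""
    faces = mesh.surfaces["outer_table"]
    pts = mesh.node_coords
    cz = pts[faces].mean(axis=1)
    cand = np.flatnonzero(
        (cz[:, 2] > 0) & (np.hypot(cz[:, 0] - x_t, cz[:, 1] - y_s) < 12.0)
    )
    best = None
    best_fallback = (np.inf, None, None)
    for fi in cand:
        tri = faces[fi]
        p0, p1, p2 = pts[tri, :2]
        M = np.column_stack([p1 - p0, p2 - p0])
        try:
            st = np.linalg.solve(M, np.array([x_t, y_s]) - p0)
        except np.linalg.LinAlgError:
            continue
        bary = np.array([1 - st.sum(), st[0], st[1]])
        viol = float(-bary.min())
        if viol <= 1e-9:
            best = (tri, bary)
            break
        if viol < best_fallback[0]:
            best_fallback = (viol, tri, np.clip(bary, 0, None))
    if best is None:
        if best_fallback[1] is None:
            raise ValueError(f"no outer-table triangle near anchor target ({x_t}, {y_s})")
        _, tri, bary = best_fallback
        bary = bary / bary.sum()
        best = (tri, bary)
    return best


def _tag_anchors(mesh: CalvarialMesh, plan: SurgeryPlan, y0: float, y1: float) -> None:
    nodes = mesh.node_coords
    n_shell = mesh.meta["n_shell_nodes"]
    shell_xyz = nodes[:n_shell]
    y_cor = mesh.meta["coronal_y"]
    half_span = plan.burr_hole_spacing / 2.0
    r_anchor = max(3.0, 0.8 * mesh.element_size())
    suture_like = set(
        ["coronal_suture", "lambdoid_suture", "squamosal_suture", "metopic_suture",
         "anterior_fontanelle", "craniotomy"]
    )
    # node -> incident labels, for the in-bone check
    for k, d in enumerate(plan.spring_positions):
        y_s = y_cor - d
        if not (y0 - 1e-9 <= y_s <= y1 + 1e-9):
            raise ValueError(
                f"spring position {d} mm from the coronal suture falls outside the "
                f"craniotomy extent ({y0:.1f}..{y1:.1f} mm)"
            )
        for side, tag in ((-1.0, "L"), (1.0, "R")):
            x_t = side * half_span
            tri, bary = _containing_surface_triangle(mesh, x_t, y_s)
            # anchor columns: the triangle's node columns through the thickness,
            # barycentric weights split evenly over the sheets
            nvs = n_shell // (mesh.meta.get("shell_layers", 2) + 1)
            n_sheets = n_shell // nvs
            cols = tri % nvs
            grp = np.concatenate([cols + s * nvs for s in range(n_sheets)])
            wts = np.tile(bary / n_sheets, n_sheets)
            seed_id = tri[np.argmax(bary)]
            touching = np.isin(mesh.tets, seed_id).any(axis=1)
            labs = set(mesh.region_labels[touching].tolist())
            if labs and labs <= suture_like:
                raise ValueError(
                    f"spring anchor at {d} mm ({tag}) falls inside {sorted(labs)}"
                )
            mesh.node_sets[f"spring_anchor_{k}_{tag}"] = grp
            mesh.meta.setdefault("spring_anchor_weights", {})[f"{k}_{tag}"] = wts


def place_springs(
    mesh: CalvarialMesh,
    plan: SurgeryPlan,
    force_at_crimp: float = 8.0,
    free_length: float = 100.0,
    crimped_length: float = 15.0,
    clamp_compression: bool = True,
) -> SpringSet:
    """Instantiate Hookean distractors on the anchor groups tagged by surgery."""
    if plan.technique == "MSC":
        raise ValueError("technique has no springs")
    K = spring_stiffness(force_at_crimp, free_length, crimped_length)
    springs = []
    for k, d in enumerate(plan.spring_positions):
        try:
            aL = mesh.node_sets[f"spring_anchor_{k}_L"]
            aR = mesh.node_sets[f"spring_anchor_{k}_R"]
        except KeyError as exc:
            raise ValueError(f"no anchors tagged for spring at {d} mm; run apply_surgery") from exc
        wmap = mesh.meta.get("spring_anchor_weights", {})
        s = Spring(
            anchors_L=aL,
            anchors_R=aR,
            weights_L=wmap.get(f"{k}_L"),
            weights_R=wmap.get(f"{k}_R"),
            free_length=free_length,
            stiffness=K,
            position_mm=d,
            clamp_compression=clamp_compression,
        )
        s.update_from_mesh(mesh.node_coords)
        springs.append(s)
    return SpringSet(springs)
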