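"""Small-strain linear-elastic tetrahedral FE kernel.

Features exactly what the growth pipeline needs: 4- or 10-node tetrahedra
with bonded (shared-node) continuity inside each body, nodal constraints in
all degrees of freedom, node-to-triangle penalty contact between the ICV
surface and the inner table (with a friction-capped tangential penalty),
Hookean spring elements between anchor node groups, and isotropic
eigenstrain (thermal-expansion analogy) loading of the ICV to drive growth.

Quadratic (10-node) elements are the default: thin-shell bending of the
calvaria locks badly with linear tetrahedra.  Midside nodes are generated
internally from the 4-node geometry mesh (straight-sided elements), so the
mesh container, surfaces, anchors and constraints all keep working with
corner-node indices; returned displacements are at corner nodes.

Units are mm-N-MPa throughout.  Each solve is geometrically linear; the
growth driver updates the geometry between load steps, which is how large
total deformations are accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

__all__ = [
    "ContactSpec",
    "LoadCase",
    "SolveResult",
    "ContactState",
    "ConvergenceError",
    "solve_static",
    "calibrate_eigenstrain",
    "contact_pressure_map",
    "reaction_forces",
    "von_mises_strain",
    "deformed_icv_volume_ml",
]

DEFAULT_FIXED_SETS = ("foramen_magnum_ring", "nasal_ridge_patch", "icv_base")

# 4-point Gauss rule on the tetrahedron (barycentric), exact for quadratics
_GA, _GB = 0.5854101966249685, 0.1381966011250105
_GPTS = np.array(
    [
        [_GA, _GB, _GB, _GB],
        [_GB, _GA, _GB, _GB],
        [_GB, _GB, _GA, _GB],
        [_GB, _GB, _GB, _GA],
    ]
)
_EDGE_LOCAL = np.array([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg + (f"; iteration trace: {trace}" if trace else ""))
        self.trace = trace or []


@dataclass
class ContactSpec:
    """Penalty contact parameters (stiffness per contact node)."""

    normal_stiffness: float = 50.0  # N/mm per slave node
    penetration_tolerance: float = 0.5  # mm
    friction_coefficient: float = 0.1

    def __post_init__(self):
        if min(self.normal_stiffness, self.penetration_tolerance, self.friction_coefficient) <= 0:
            raise ValueError("contact parameters must be positive")


@dataclass
class LoadCase:
    """One quasi-static load step: ICV eigenstrain + active springs."""

    eigenstrain: float = 0.0
    springs: Optional[object] = None  # SpringSet
    fixed_sets: Sequence[str] = DEFAULT_FIXED_SETS

    def __post_init__(self):
        if self.eigenstrain < 0:
            raise ValueError("eigenstrain must be >= 0")
        if not self.fixed_sets:
            raise ValueError("constraint sets must be non-empty")


@dataclass
class ContactState:
    slave_nodes: np.ndarray
    master_faces: np.ndarray  # (npair, 3) node ids
    weights: np.ndarray  # (npair, 3) barycentric
    normals: np.ndarray  # (npair, 3) pointing from master toward the ICV side
    gap0: np.ndarray
    gaps: np.ndarray
    active: np.ndarray
    normal_force: np.ndarray  # N per slave node (positive in compression)
    stiffness_scale: float = 1.0


@dataclass
class SolveResult:
    displacement: np.ndarray  # (n_corner_nodes, 3)
    contact: Optional[ContactState]
    residual_full: np.ndarray
    iterations: int
    spring_forces: list = field(default_factory=list)
    trace: list = field(default_factory=list)
    n_corner: int = 0


# ---------------------------------------------------------------------------
# Elements
# ---------------------------------------------------------------------------


def _elastic_tensors(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    m = len(E)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((m, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _bary_grads(nodes: np.ndarray, tets: np.ndarray):
    """Constant barycentric gradients and volumes of straight-sided tets."""
    x = nodes[tets[:, :4]]
    J = x[:, 1:] - x[:, :1]
    detJ = np.linalg.det(J)
    vols = detJ / 6.0
    if np.any(vols <= 0):
        bad = np.flatnonzero(vols <= 0)[:5]
        raise ValueError(f"non-positive tetrahedra in FE assembly: {bad.tolist()}")
    Jinv = np.linalg.inv(J)
    g123 = np.transpose(Jinv, (0, 2, 1))
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vols  # (m,4,3)


def _strain_matrix(dN: np.ndarray) -> np.ndarray:
    """B (m,6,3k) from shape-function gradients dN (m,k,3)."""
    m, k, _ = dN.shape
    B = np.zeros((m, 6, 3 * k))
    gx, gy, gz = dN[:, :, 0], dN[:, :, 1], dN[:, :, 2]
    c = 3 * np.arange(k)
    B[:, 0, c] = gx
    B[:, 1, c + 1] = gy
    B[:, 2, c + 2] = gz
    B[:, 3, c] = gy
    B[:, 3, c + 1] = gx
    B[:, 4, c + 1] = gz
    B[:, 4, c + 2] = gy
    B[:, 5, c] = gz
    B[:, 5, c + 2] = gx
    return B


def _tet10_dN(gl: np.ndarray, L: np.ndarray) -> np.ndarray:
    """TET10 shape gradients at barycentric point L. gl: (m,4,3)."""
    m = gl.shape[0]
    dN = np.empty((m, 10, 3))
    for i in range(4):
        dN[:, i] = (4 * L[i] - 1) * gl[:, i]
    for e, (a, b) in enumerate(_EDGE_LOCAL):
        dN[:, 4 + e] = 4 * (L[b] * gl[:, a] + L[a] * gl[:, b])
    return dN


def quad_element_mask(mesh, order) -> np.ndarray:
    """Which elements are assembled as 10-node tets.

    ``order=2`` promotes the shell (everything except the bulky ICV, whose
    response is compression-dominated and does not lock) to quadratic.
    """
    if order == 1:
        return np.zeros(len(mesh.tets), dtype=bool)
    return np.asarray(mesh.region_labels) != "icv"


def mesh_edges(mesh, quad_mask) -> np.ndarray:
    """Unique node-pair edges of the quadratic elements (cached on the mesh)."""
    key = int(quad_mask.sum())
    cached = getattr(mesh, "_edge_cache", None)
    if cached is not None and cached[0] == key:
        return cached[1], cached[2]
    tets = np.asarray(mesh.tets)[quad_mask]
    pairs = np.sort(tets[:, _EDGE_LOCAL].reshape(-1, 2), axis=1)
    edges, inv = np.unique(pairs, axis=0, return_inverse=True)
    mesh._edge_cache = (key, edges, inv.reshape(-1, 6))
    return edges, inv.reshape(-1, 6)


def assemble_stiffness(nodes, tets, E, nu, order: int = 2, mesh=None, quad_mask=None):
    """Global stiffness (csr) and an assembly cache for load evaluation.

    Quadratic elements get midside DOFs appended after the corner DOFs
    (straight-sided TET10, 4-point Gauss); the remaining elements are
    constant-strain TET4.  ``quad_mask`` defaults to all (order 2) or none
    (order 1); when a mesh is given, its ICV stays linear.
    """
    tets = np.asarray(tets)
    D = _elastic_tensors(np.asarray(E, float), np.asarray(nu, float))
    gl, vols = _bary_grads(nodes, tets)
    n_corner = len(nodes)
    if quad_mask is None:
        if mesh is not None:
            quad_mask = quad_element_mask(mesh, order)
        else:
            quad_mask = np.full(len(tets), order == 2)
    quad_mask = np.asarray(quad_mask, bool)

    batches = []  # (element indices, dof (m,3k), Bbar (m,6,3k))
    n_total = n_corner
    if quad_mask.any():
        qi = np.flatnonzero(quad_mask)
        if mesh is not None:
            edges, e_inv = mesh_edges(mesh, quad_mask)
        else:
            pairs = np.sort(tets[qi][:, _EDGE_LOCAL].reshape(-1, 2), axis=1)
            edges, inv = np.unique(pairs, axis=0, return_inverse=True)
            e_inv = inv.reshape(-1, 6)
        conn = np.hstack([tets[qi], e_inv + n_corner])
        n_total = n_corner + len(edges)
        Ke = None
        Bbar = np.zeros((len(qi), 6, 30))
        glq, vq, Dq = gl[qi], vols[qi], D[qi]
        for gp in _GPTS:
            Bg = _strain_matrix(_tet10_dN(glq, gp))
            term = np.einsum("eai,eab,ebj->eij", Bg, Dq, Bg) * (vq[:, None, None] / 4.0)
            Ke = term if Ke is None else Ke + term
            Bbar += Bg / 4.0
        dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(len(qi), 30)
        batches.append((qi, dof, Bbar, Ke))
    if (~quad_mask).any():
        li = np.flatnonzero(~quad_mask)
        B = _strain_matrix(gl[li])
        Ke = np.einsum("eai,eab,ebj->eij", B, D[li], B) * vols[li, None, None]
        dof = (3 * tets[li][:, :, None] + np.arange(3)[None, None, :]).reshape(len(li), 12)
        batches.append((li, dof, B, Ke))

    n3 = 3 * n_total
    rows, cols, vals = [], [], []
    for _, dof, _, Ke in batches:
        k = dof.shape[1]
        rows.append(np.repeat(dof, k, axis=1).ravel())
        cols.append(np.tile(dof, (1, k)).ravel())
        vals.append(Ke.ravel())
    K = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n3, n3)
    ).tocsr()
    cache = {
        "vols": vols,
        "D": D,
        "batches": [(idx, dof, Bbar) for idx, dof, Bbar, _ in batches],
        "n_corner": n_corner,
        "n_total": n_total,
        "order": order,
        "quad_mask": quad_mask,
    }
    return K, cache


def eigenstrain_load(cache, icv_mask: np.ndarray, eps: float) -> np.ndarray:
    """Consistent nodal loads from isotropic stress-free expansion of the ICV."""
    f = np.zeros(3 * cache["n_total"])
    if eps == 0.0:
        return f
    e0 = np.array([eps, eps, eps, 0.0, 0.0, 0.0])
    for idx, dof, Bbar in cache["batches"]:
        in_icv = icv_mask[idx]
        if not in_icv.any():
            continue
        sel = np.flatnonzero(in_icv)
        sig0 = cache["D"][idx[sel]] @ e0
        fe = np.einsum("eai,ea->ei", Bbar[sel], sig0) * cache["vols"][idx[sel], None]
        np.add.at(f, dof[sel].ravel(), fe.ravel())
    return f


def von_mises_strain(nodes, tets, u_corner: np.ndarray) -> np.ndarray:
    """Per-element equivalent (von Mises) strain from corner displacements."""
    gl, _ = _bary_grads(nodes, tets)
    B = _strain_matrix(gl)
    ue = u_corner.reshape(-1, 3)[tets].reshape(len(tets), 12)
    e = np.einsum("eab,eb->ea", B, ue)
    exx, eyy, ezz, gxy, gyz, gzx = e.T
    tr = (exx + eyy + ezz) / 3.0
    dxx, dyy, dzz = exx - tr, eyy - tr, ezz - tr
    j2 = 0.5 * (dxx**2 + dyy**2 + dzz**2) + (gxy / 2) ** 2 + (gyz / 2) ** 2 + (gzx / 2) ** 2
    return np.sqrt(4.0 / 3.0 * j2)


# ---------------------------------------------------------------------------
# Contact pairing
# ---------------------------------------------------------------------------


def _point_triangle_project(p, a, b, c):
    """Closest point on triangle abc to p (vectorised over leading axis)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = np.where(np.abs(va + vb + vc) < 1e-300, 1.0, va + vb + vc)
    w = np.stack([va, vb, vc], axis=1) / denom[:, None]
    w = np.clip(w, 0.0, 1.0)
    w /= w.sum(axis=1, keepdims=True)
    m1 = (d1 <= 0) & (d2 <= 0)
    w[m1] = [1, 0, 0]
    m2 = (d3 >= 0) & (d4 <= d3)
    w[m2] = [0, 1, 0]
    m3 = (d6 >= 0) & (d5 <= d6)
    w[m3] = [0, 0, 1]
    v_ab = d1 * d4 - d3 * d2
    m4 = (v_ab <= 0) & (d1 >= 0) & (d3 <= 0) & ~(m1 | m2 | m3)
    t = d1 / np.where(np.abs(d1 - d3) < 1e-300, 1.0, d1 - d3)
    w[m4] = np.stack([1 - t, t, np.zeros_like(t)], axis=1)[m4]
    proj = w[:, 0:1] * a + w[:, 1:2] * b + w[:, 2:3] * c
    return proj, w


def build_contact_state(mesh, spec: ContactSpec) -> Optional[ContactState]:
    if "icv_surface" not in mesh.surfaces or "inner_table" not in mesh.surfaces:
        return None
    slave = np.unique(mesh.surfaces["icv_surface"])
    master = mesh.surfaces["inner_table"]
    pts = mesh.node_coords
    mc = pts[master].mean(axis=1)
    tree = cKDTree(mc)
    k = min(8, len(mc))
    _, cand = tree.query(pts[slave], k=k)
    cand = np.atleast_2d(cand)
    best_d = np.full(len(slave), np.inf)
    best_face = np.zeros(len(slave), dtype=np.int64)
    best_w = np.zeros((len(slave), 3))
    best_proj = np.zeros((len(slave), 3))
    p = pts[slave]
    for col in range(cand.shape[1]):
        f = master[cand[:, col]]
        proj, w = _point_triangle_project(p, pts[f[:, 0]], pts[f[:, 1]], pts[f[:, 2]])
        d = np.linalg.norm(p - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_face[better] = cand[better, col]
        best_w[better] = w[better]
        best_proj[better] = proj[better]
    faces = master[best_face]
    # inner_table triangles are wound so their normal points toward the ICV
    n = np.cross(pts[faces[:, 1]] - pts[faces[:, 0]], pts[faces[:, 2]] - pts[faces[:, 0]])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    gap0 = np.einsum("ij,ij->i", p - best_proj, n)
    # remove the as-built discretization bias (the two surfaces triangulate
    # the same smooth interface at different resolutions, so their nominal
    # gap is zero: chord offsets recorded at generation time are not contact)
    bias_nodes = mesh.meta.get("contact_bias_nodes")
    if bias_nodes is not None:
        bias = np.zeros(len(pts))
        bias[bias_nodes] = mesh.meta["contact_bias_values"]
        gap0 = gap0 - bias[slave]
    return ContactState(
        slave_nodes=slave,
        master_faces=faces,
        weights=best_w,
        normals=n,
        gap0=gap0,
        gaps=gap0.copy(),
        active=gap0 <= 1e-9,
        normal_force=np.zeros(len(slave)),
    )


def _contact_system(cs: ContactState, spec: ContactSpec, kt: np.ndarray, n3: int):
    """Penalty stiffness and load for the active pairs."""
    act = np.flatnonzero(cs.active)
    if len(act) == 0:
        return csr_matrix((n3, n3)), np.zeros(n3)
    k_n = spec.normal_stiffness * cs.stiffness_scale
    f = np.zeros(n3)
    sl = cs.slave_nodes[act]
    nf = cs.master_faces[act]
    w = cs.weights[act]
    nrm = cs.normals[act]
    g0 = cs.gap0[act]
    ids = np.concatenate([sl[:, None], nf], axis=1)  # (na,4)
    coef = np.concatenate([np.ones((len(act), 1)), -w], axis=1)
    dof = (3 * ids[:, :, None] + np.arange(3)[None, None, :]).reshape(len(act), 12)
    a = (coef[:, :, None] * nrm[:, None, :]).reshape(len(act), 12)
    Ke = k_n * a[:, :, None] * a[:, None, :]
    fp = -(k_n * g0)[:, None] * a
    # tangential penalty (I - n n^T) between the pair, capped by friction
    T = np.eye(3)[None] - nrm[:, :, None] * nrm[:, None, :]
    cc = coef[:, :, None] * coef[:, None, :]  # (na,4,4)
    Kt = cc[:, :, :, None, None] * (kt[act, None, None, None, None] * T[:, None, None])
    Ke = Ke + Kt.transpose(0, 1, 3, 2, 4).reshape(len(act), 12, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = coo_matrix((Ke.ravel(), (rows, cols)), shape=(n3, n3)).tocsr()
    np.add.at(f, dof.ravel(), fp.ravel())
    return K, f


def _spring_forces_vector(nodes, springs, n3: int, forces: np.ndarray):
    """Nodal load vector for the current spring force magnitudes.

    Springs enter as iterated follower forces; their own stiffness
    (~0.1 N/mm) is negligible against the calvaria and is handled by the
    fixed-point update of the force magnitude instead of a tangent term.
    """
    f = np.zeros(n3)
    for s, f0 in zip(springs.active_springs(), forces):
        if f0 == 0.0:
            continue
        n = s.direction(nodes)
        ids = np.concatenate([s.anchors_R, s.anchors_L])
        coef = np.concatenate([s._w("R"), -s._w("L")])
        a = (coef[:, None] * n[None, :]).ravel()
        dof = (3 * ids[:, None] + np.arange(3)[None, :]).ravel()
        np.add.at(f, dof, f0 * a)  # anchor groups may share nodes
    return f


# ---------------------------------------------------------------------------
# Static solve
# ---------------------------------------------------------------------------


def _fixed_dofs(mesh, fixed_sets, cache) -> np.ndarray:
    ids = []
    if "unused_nodes" in mesh.node_sets:
        fixed_sets = tuple(fixed_sets) + ("unused_nodes",)
    for name in fixed_sets:
        if name not in mesh.node_sets:
            raise ValueError(f"constraint node set {name!r} missing: system would be singular")
        ids.append(np.asarray(mesh.node_sets[name]))
    nodes = np.unique(np.concatenate(ids))
    if cache["quad_mask"].any():
        edges, _ = mesh_edges(mesh, cache["quad_mask"])
        inset = np.zeros(cache["n_corner"], dtype=bool)
        inset[nodes] = True
        mid = np.flatnonzero(inset[edges[:, 0]] & inset[edges[:, 1]]) + cache["n_corner"]
        nodes = np.concatenate([nodes, mid])
    return (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()


def solve_static(
    mesh,
    state,
    load: LoadCase,
    contact: Optional[ContactSpec] = None,
    extra_forces: Optional[np.ndarray] = None,
    max_iter: int = 25,
    u_tol: float = 2e-3,
    order: int = 2,
    stiffness_cache=None,
    max_factorizations: int = 2,
    warm: Optional[dict] = None,
) -> SolveResult:
    """Equilibrium solve for one load step.

    Iterates the contact active set (escalating the penalty stiffness until
    the maximum penetration is within tolerance), the friction cap and the
    spring force consistency; raises ``ConvergenceError`` with an iteration
    trace if the loop does not settle.
    """
    nodes = mesh.node_coords
    if stiffness_cache is None:
        K_bulk, cache = assemble_stiffness(
            nodes, mesh.tets, state.elastic_modulus, state.poisson_ratio, order=order, mesh=mesh
        )
    else:
        K_bulk, cache = stiffness_cache
    n3 = 3 * cache["n_total"]
    icv_mask = mesh.region_labels == "icv"
    f_base = eigenstrain_load(cache, icv_mask, load.eigenstrain)
    if extra_forces is not None:
        ef = np.asarray(extra_forces).ravel()
        f_base[: len(ef)] += ef

    fixed = _fixed_dofs(mesh, load.fixed_sets, cache)
    free = np.setdiff1d(np.arange(n3), fixed)

    cs = build_contact_state(mesh, contact) if contact is not None else None
    springs = load.springs
    n_springs = len(springs.active_springs()) if springs is not None else 0
    sf_mag = np.array(
        [s.stiffness * (s.free_length - s.distance) for s in springs.active_springs()]
    ) if n_springs else np.zeros(0)
    if n_springs and springs.active_springs()[0].clamp_compression:
        sf_mag = np.maximum(sf_mag, 0.0)
    kt = None
    if cs is not None:
        # friction stiffness grows toward the mu*N cap from zero, so an
        # unloaded interface slides freely
        kt = np.zeros(len(cs.slave_nodes))
        if warm and warm.get("kt") is not None and len(warm["kt"]) == len(kt):
            kt = warm["kt"].copy()
            cs.active = warm["active"].copy()
            # re-enter with a moderated penalty; escalate again if needed
            cs.stiffness_scale = min(warm.get("scale", 1.0), 64.0)

    u = np.zeros(n3)
    trace: list = []
    prev_u = None
    prev_active = cs.active.copy() if cs is not None else None
    spring_forces: list = []
    K_tot = K_bulk
    f_tot = f_base
    lu = None
    K_dirty = True
    n_fact = 0
    for it in range(max_iter):
        if K_dirty:
            K_tot = K_bulk
            f_contact = np.zeros(n3)
            if cs is not None:
                Kc, f_contact = _contact_system(cs, contact, kt, n3)
                K_tot = K_tot + Kc
            Kff = K_tot[free][:, free].tocsc()
            try:
                lu = splu(Kff, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
            except RuntimeError as exc:
                raise ConvergenceError(f"singular stiffness system: {exc}", trace) from exc
            n_fact += 1
            K_dirty = False
        f_tot = f_base + f_contact
        if n_springs:
            f_tot += _spring_forces_vector(nodes, springs, n3, sf_mag)
        u = np.zeros(n3)
        u[free] = lu.solve(f_tot[free])

        converged = True
        note = {"iter": it}
        if cs is not None:
            du = u.reshape(-1, 3)
            rel = du[cs.slave_nodes] - np.einsum("pk,pkj->pj", cs.weights, du[cs.master_faces])
            cs.gaps = cs.gap0 + np.einsum("pj,pj->p", rel, cs.normals)
            new_active = cs.gaps < 0
            k_n = contact.normal_stiffness * cs.stiffness_scale
            cs.normal_force = np.where(new_active, -cs.gaps * k_n, 0.0)
            pen = float(np.maximum(0.0, -cs.gaps).max(initial=0.0))
            note.update(pen=round(pen, 4), n_active=int(new_active.sum()))
            if pen > contact.penetration_tolerance:
                if cs.stiffness_scale < 4**6:
                    cs.stiffness_scale *= 4.0
                    converged = False
                    K_dirty = True
                    note["escalate"] = cs.stiffness_scale
                else:
                    raise ConvergenceError("contact penetration not controllable", trace)
            n_changed = int(np.sum(new_active != prev_active))
            if n_changed > max(2, 0.005 * len(new_active)) and n_fact < max_factorizations:
                converged = False
                K_dirty = True
            note["flips"] = n_changed
            prev_active = new_active
            cs.active = new_active
            # friction cap: secant update of the tangential penalty stiffness
            t_rel = rel - np.einsum("pj,pj->p", rel, cs.normals)[:, None] * cs.normals
            t_mag = np.linalg.norm(t_rel, axis=1)
            cap = contact.friction_coefficient * cs.normal_force
            kt_new = np.zeros_like(kt)
            kt_new[new_active] = np.minimum(
                contact.normal_stiffness, cap[new_active] / np.maximum(t_mag[new_active], 1e-9)
            )
            rel_change = np.max(np.abs(kt_new - kt)) / contact.normal_stiffness
            note["kt_change"] = round(float(rel_change), 4)
            if rel_change > 0.3 and it < max_iter - 2 and n_fact < max_factorizations:
                converged = False
                K_dirty = True
                kt = kt_new
        if n_springs:
            du = u.reshape(-1, 3)
            spring_forces = []
            sf_new = np.zeros(n_springs)
            for s_idx, s in enumerate(springs.active_springs()):
                cL, cR = s.leg_points(nodes)
                dL = s._w("L") @ du[s.anchors_L]
                dR = s._w("R") @ du[s.anchors_R]
                d_new = float(np.linalg.norm((cR + dR) - (cL + dL)))
                f_new = s.stiffness * (s.free_length - d_new)
                if s.clamp_compression and f_new < 0:
                    f_new = 0.0
                sf_new[s_idx] = f_new
                spring_forces.append((s.position_mm, d_new, f_new))
            if np.max(np.abs(sf_new - sf_mag), initial=0.0) > 0.02:
                converged = False
            sf_mag = sf_new
        if prev_u is not None:
            scale = max(1e-9, float(np.abs(u).max()))
            dumax = float(np.abs(u - prev_u).max()) / scale
            note["du"] = round(dumax, 6)
            if dumax > u_tol:
                converged = False
        else:
            converged = False
        trace.append(note)
        prev_u = u
        if converged:
            break
    else:
        raise ConvergenceError("contact/spring iteration did not converge", trace)

    if warm is not None and cs is not None:
        warm["kt"] = kt.copy()
        warm["active"] = cs.active.copy()
        warm["scale"] = cs.stiffness_scale
    r = K_tot @ u - f_tot
    n_corner = cache["n_corner"]
    return SolveResult(
        displacement=u[: 3 * n_corner].reshape(-1, 3),
        contact=cs,
        residual_full=r,
        iterations=len(trace),
        spring_forces=spring_forces,
        trace=trace,
        n_corner=n_corner,
    )


def deformed_icv_volume_ml(mesh, u: np.ndarray) -> float:
    nodes = mesh.node_coords + u
    sel = mesh.region_labels == "icv"
    x = nodes[mesh.tets[sel]]
    return float((np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0).sum() / 1000.0)


def calibrate_eigenstrain(
    mesh,
    state,
    contact: Optional[ContactSpec],
    target_icv_ml: float,
    springs=None,
    fixed_sets=DEFAULT_FIXED_SETS,
    rel_tol: float = 0.005,
    max_eval: int = 12,
    eps_max: float = 2.0,
    order: int = 2,
    eps0: Optional[float] = None,
    warm: Optional[dict] = None,
):
    """Find the isotropic ICV eigenstrain that reaches a target deformed volume.

    Scalar secant iteration starting from the free-expansion estimate
    (V*/V)^(1/3) - 1; every evaluation is one full contact solve.  Returns
    ``(LoadCase, SolveResult)`` at the calibrated eigenstrain.
    """
    v0 = mesh.icv_volume_ml()
    if target_icv_ml < v0 * (1 - 1e-6):
        raise ValueError(f"target ICV {target_icv_ml} ml below current volume {v0:.1f} ml")
    cache = assemble_stiffness(
        mesh.node_coords, mesh.tets, state.elastic_modulus, state.poisson_ratio,
        order=order, mesh=mesh,
    )

    if warm is None:
        warm = {}

    def run(eps):
        lc = LoadCase(eigenstrain=eps, springs=springs, fixed_sets=fixed_sets)
        # with a warmed contact state a single factorization per solve is
        # enough; a cold start gets one extra to discover the active set
        res = solve_static(
            mesh, state, lc, contact, stiffness_cache=cache, order=order, warm=warm,
            max_factorizations=1 if warm.get("kt") is not None else 2,
        )
        return lc, res, deformed_icv_volume_ml(mesh, res.displacement)

    if eps0 is None:
        eps0 = max((target_icv_ml / v0) ** (1.0 / 3.0) - 1.0, 0.0)
    if eps0 < 1e-9:
        return run(0.0)[:2]
    lc, res, v = run(eps0)
    if abs(v - target_icv_ml) <= rel_tol * target_icv_ml:
        return lc, res
    e_prev, v_prev = 0.0, v0
    e_cur, v_cur = eps0, v
    for _ in range(max_eval):
        slope = (v_cur - v_prev) / (e_cur - e_prev)
        if slope <= 0:
            raise ConvergenceError("eigenstrain calibration lost its bracket (non-monotone volume)")
        e_next = e_cur + (target_icv_ml - v_cur) / slope
        # trust region: a stiffening shell can make the secant slope tiny
        e_next = float(np.clip(e_next, 0.0, min(eps_max, 3.0 * e_cur + 0.05)))
        lc, res, v_next = run(e_next)
        if abs(v_next - target_icv_ml) <= rel_tol * target_icv_ml:
            return lc, res
        e_prev, v_prev = e_cur, v_cur
        e_cur, v_cur = e_next, v_next
        if e_cur >= eps_max and v_cur < target_icv_ml:
            raise ConvergenceError(
                f"target ICV {target_icv_ml} ml unreachable with eigenstrain <= {eps_max}"
            )
    raise ConvergenceError(
        f"eigenstrain calibration did not reach {target_icv_ml} ml "
        f"(best {v_cur:.1f} ml at eps={e_cur:.4f})"
    )


def contact_pressure_map(mesh, result: SolveResult, contact: ContactSpec) -> np.ndarray:
    """Normal contact pressure (MPa) per icv_surface face; zero where separated."""
    faces = mesh.surfaces["icv_surface"]
    pts = mesh.node_coords
    cs = result.contact
    node_p = np.zeros(len(pts))
    if cs is not None:
        areas = 0.5 * np.linalg.norm(
            np.cross(pts[faces[:, 1]] - pts[faces[:, 0]], pts[faces[:, 2]] - pts[faces[:, 0]]),
            axis=1,
        )
        node_area = np.zeros(len(pts))
        for k in range(3):
            np.add.at(node_area, faces[:, k], areas / 3.0)
        nz = node_area[cs.slave_nodes] > 0
        node_p[cs.slave_nodes[nz]] = cs.normal_force[nz] / node_area[cs.slave_nodes[nz]]
    return node_p[faces].mean(axis=1)


def reaction_forces(mesh, result: SolveResult, fixed_sets=DEFAULT_FIXED_SETS) -> dict:
    """Net reaction force (N) on each constrained node set.

    Midside-node contributions on set-internal edges are folded into the set
    sums so global equilibrium holds for quadratic elements too.
    """
    r = result.residual_full.reshape(-1, 3)
    n_corner = result.n_corner
    out = {}
    total = np.zeros(3)
    ec = getattr(mesh, "_edge_cache", None)
    edges = ec[1] if ec is not None else None
    for name in fixed_sets:
        ids = np.asarray(mesh.node_sets[name])
        f = r[ids].sum(axis=0)
        if edges is not None and len(r) > n_corner:
            inset = np.zeros(n_corner, dtype=bool)
            inset[ids] = True
            mid = np.flatnonzero(inset[edges[:, 0]] & inset[edges[:, 1]]) + n_corner
            f = f + r[mid].sum(axis=0)
        out[name] = f
        total += f
    out["total"] = total
    return out
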