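"""Material table, spring constitutive law and ossification-front bone formation.

Elastic properties follow the infant-calvaria literature values used for
craniosynostosis growth models: bone plates 421 MPa, patent sutures and
fontanelle 30 MPa, craniotomy (healing defect tissue) 0.3 MPa and the
intracranial volume (ICV, the growing "brain" domain) 10 MPa, with Poisson
ratios of 0.3 for bone/sutures and 0.1 for ICV/craniotomy.

Bone formation is modelled as an ossification front that advances from the
bone--suture and bone--craniotomy linings at a prescribed speed (mm per month
of simulated growth).  Elements convert to bone when the cumulative front
travel reaches their geodesic distance from the lining; converted elements
then stiffen by a fixed modulus ramp per month, and original bone stiffens by
its own (faster) ramp.  The metopic suture and the anterior fontanelle do not
heal by front propagation; they are prescribed to be fully formed at a set
age (default 24 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BONE_LABELS",
    "SUTURE_LABELS",
    "FRONT_HEALING_SUTURES",
    "PRESCRIBED_CLOSURE_LABELS",
    "MATERIAL_TABLE",
    "MaterialState",
    "OssificationRule",
    "Spring",
    "SpringSet",
    "default_material_state",
    "spring_stiffness",
    "spring_force",
    "advance_ossification",
    "closure_fraction",
]

# Region labels understood by the material table.  The lateral plates below the
# squamosal sutures and the basal plate are bone-valued like the named vault
# plates.
BONE_LABELS = frozenset(
    {
        "frontal_L",
        "frontal_R",
        "parietal_L",
        "parietal_R",
        "occipital",
        "temporal_L",
        "temporal_R",
        "fused_sagittal",
    }
)
SUTURE_LABELS = frozenset(
    {
        "coronal_suture",
        "lambdoid_suture",
        "squamosal_suture",
        "metopic_suture",
        "anterior_fontanelle",
    }
)
# Sutures that heal by front propagation (the metopic suture and the anterior
# fontanelle close by prescription instead).
FRONT_HEALING_SUTURES = ("coronal_suture", "lambdoid_suture", "squamosal_suture")
PRESCRIBED_CLOSURE_LABELS = ("metopic_suture", "anterior_fontanelle")

# label -> (elastic modulus MPa, Poisson ratio).  The basal plate is the
# infant cranial base: it deforms at its cartilaginous synchondroses, so it
# carries suture-grade stiffness and never ossifies in the simulated window
# (the vault would otherwise seal into a rigid ball once the sutures close,
# leaving late brain growth nowhere to go).
MATERIAL_TABLE: dict[str, tuple[float, float]] = {
    **{lab: (421.0, 0.3) for lab in BONE_LABELS},
    **{lab: (30.0, 0.3) for lab in SUTURE_LABELS},
    "basal_plate": (30.0, 0.3),
    "craniotomy": (0.3, 0.1),
    "icv": (10.0, 0.1),
}


@dataclass
class OssificationRule:
    """Rates (mm/month) and modulus ramps (MPa/month) for bone formation."""

    suture_front_rate: float = 0.2
    craniotomy_front_rate: float = 10.8
    new_bone_ramp: float = 100.0
    bone_ramp: float = 125.0
    prescribed_closure_age: float = 24.0

    def validate(self, start_age: float = 0.0) -> None:
        for name in ("suture_front_rate", "craniotomy_front_rate", "new_bone_ramp", "bone_ramp"):
            if getattr(self, name) < 0:
                raise ValueError(f"ossification rate {name!r} must be >= 0")
        if self.prescribed_closure_age <= start_age:
            raise ValueError("prescribed closure age must exceed the simulation start age")


@dataclass
class MaterialState:
    """Per-element elastic state evolving over simulated months.

    ``tissue`` keeps the element labels at the time the state was created
    (i.e. after virtual surgery), so healed craniotomy elements remain
    attributable to the craniotomy region.  ``ossified_since`` is NaN for
    unossified soft tissue; original bone carries the state creation age.
    """

    elastic_modulus: np.ndarray
    poisson_ratio: np.ndarray
    ossified_since: np.ndarray
    tissue: np.ndarray
    age: float
    # remaining geodesic front-travel distance per element (mm); NaN until the
    # element's tissue group is activated by a first advance call
    front_distance: np.ndarray = field(default=None)  # type: ignore[assignment]
    front_travel: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.front_distance is None:
            self.front_distance = np.full(self.elastic_modulus.shape, np.nan)

    @property
    def ossified(self) -> np.ndarray:
        return ~np.isnan(self.ossified_since)

    def copy(self) -> "MaterialState":
        return MaterialState(
            self.elastic_modulus.copy(),
            self.poisson_ratio.copy(),
            self.ossified_since.copy(),
            self.tissue.copy(),
            self.age,
            self.front_distance.copy(),
            dict(self.front_travel),
        )


def default_material_state(mesh, age: float = 4.0) -> MaterialState:
    """Assign the default material table to a labeled mesh.

    Raises ``KeyError`` naming any region label absent from the table.
    """
    labels = np.asarray(mesh.region_labels)
    E = np.empty(len(labels))
    nu = np.empty(len(labels))
    for lab in np.unique(labels):
        if lab not in MATERIAL_TABLE:
            raise KeyError(f"unknown region label {lab!r}: no material assigned")
        e, p = MATERIAL_TABLE[lab]
        sel = labels == lab
        E[sel] = e
        nu[sel] = p
    ossified_since = np.full(len(labels), np.nan)
    is_bone = np.isin(labels, sorted(BONE_LABELS))
    ossified_since[is_bone] = age
    return MaterialState(E, nu, ossified_since, labels.copy(), age)


def spring_stiffness(force_at_crimp: float, free_length: float, crimped_length: float) -> float:
    """Hookean stiffness K = f/dx from a single crimp measurement."""
    if force_at_crimp <= 0:
        raise ValueError("crimp force must be positive")
    dx = free_length - crimped_length
    if dx <= 0 or crimped_length <= 0:
        raise ValueError("free length must exceed (positive) crimped length")
    return force_at_crimp / dx


@dataclass
class Spring:
    """A Hookean distractor between two anchor node groups."""

    anchors_L: np.ndarray
    anchors_R: np.ndarray
    weights_L: Optional[np.ndarray] = None
    weights_R: Optional[np.ndarray] = None
    free_length: float = 100.0
    stiffness: float = 8.0 / 85.0
    distance: float = 15.0
    force: float = 8.0
    active: bool = True
    removed: bool = False
    position_mm: float = 0.0  # distance from the coronal suture
    clamp_compression: bool = True

    def _w(self, side: str) -> np.ndarray:
        ids = self.anchors_L if side == "L" else self.anchors_R
        w = self.weights_L if side == "L" else self.weights_R
        if w is None:
            w = np.full(len(ids), 1.0 / len(ids))
        return w

    def leg_points(self, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cL = self._w("L") @ nodes[self.anchors_L]
        cR = self._w("R") @ nodes[self.anchors_R]
        return cL, cR

    def update_from_mesh(self, nodes: np.ndarray) -> None:
        cL, cR = self.leg_points(nodes)
        self.distance = float(np.linalg.norm(cR - cL))
        self.force = spring_force(self)

    def direction(self, nodes: np.ndarray) -> np.ndarray:
        cL, cR = self.leg_points(nodes)
        d = cR - cL
        return d / np.linalg.norm(d)


@dataclass
class SpringSet:
    springs: list

    def __iter__(self):
        return iter(self.springs)

    def __len__(self):
        return len(self.springs)

    def active_springs(self):
        return [s for s in self.springs if s.active]

    def remove_all(self) -> None:
        for s in self.springs:
            s.active = False
            s.removed = True
            s.force = 0.0

    def update_from_mesh(self, nodes: np.ndarray) -> None:
        for s in self.springs:
            if not s.removed:
                s.update_from_mesh(nodes)


def spring_force(spring: Spring) -> float:
    """f = K (L0 - d) for an active spring, 0 for an inactive one.

    If the opening exceeds the free length the linear law gives a compressive
    (negative) force; physically the spring disengages, so by default the
    force is clamped at zero (configurable per spring).
    """
    if not spring.active:
        return 0.0
    if spring.distance <= 0:
        raise ValueError("spring leg-to-leg distance must be positive")
    f = spring.stiffness * (spring.free_length - spring.distance)
    if f < 0 and spring.clamp_compression:
        return 0.0
    return f


# ---------------------------------------------------------------------------
# Ossification front propagation
# ---------------------------------------------------------------------------


def _tet_adjacency(mesh):
    """Face-sharing tet adjacency as (i, j) index arrays; cached on the mesh."""
    cached = getattr(mesh, "_tet_adjacency", None)
    if cached is not None:
        return cached
    tets = np.asarray(mesh.tets)
    m = len(tets)
    faces = np.concatenate(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    owner = np.tile(np.arange(m), 4)
    faces = np.sort(faces, axis=1)
    order = np.lexsort(faces.T)
    faces = faces[order]
    owner = owner[order]
    same = np.all(faces[1:] == faces[:-1], axis=1)
    i = owner[:-1][same]
    j = owner[1:][same]
    adj = (np.concatenate([i, j]), np.concatenate([j, i]))
    mesh._tet_adjacency = adj
    return adj


def _front_distances(mesh, candidate: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Distance (mm) of each candidate element from the ossified lining.

    Measured as Euclidean centroid distance to the nearest ossified element,
    corrected by half the local element size so that elements touching the
    interface start at roughly zero.  (Centroid-graph path lengths are not
    used: their lattice tortuosity overestimates physical front travel.)
    """
    from scipy.spatial import cKDTree

    cent = mesh.element_centroids()
    out = np.full(len(cent), np.inf)
    if not source.any() or not candidate.any():
        return out
    tree = cKDTree(cent[source])
    d, _ = tree.query(cent[candidate])
    h_half = 0.5 * mesh.element_size()
    out[candidate] = np.maximum(d - h_half, 0.0)
    return out


def advance_ossification(
    mesh,
    state: MaterialState,
    rule: OssificationRule,
    from_age: float,
    to_age: float,
) -> MaterialState:
    """Advance fronts and stiffness ramps over (from_age, to_age] months.

    Processing is month-by-month internally (fractional end intervals scale
    linearly), so one call over n months is identical to n one-month calls on
    fixed geometry.  Front distances are measured on the geometry current at
    activation and are only ever *raised* when later deformation stretches the
    region (healing cannot gain ground from a widening defect).
    """
    if to_age < from_age:
        raise ValueError("negative ossification interval")
    state = state.copy()
    if to_age == from_age:
        return state
    rule.validate()

    groups = [(("craniotomy",), rule.craniotomy_front_rate)]
    groups.append((FRONT_HEALING_SUTURES, rule.suture_front_rate))

    # (re)measure front distances on current geometry; only raise existing ones
    for labels, _rate in groups:
        cand = np.isin(state.tissue, labels) & ~state.ossified
        if not cand.any():
            continue
        dist = _front_distances(mesh, cand, state.ossified)
        old = state.front_distance
        take_new = cand & (np.isnan(old) | (dist > old))
        state.front_distance[take_new] = dist[take_new]
        for lab in labels:
            state.front_travel.setdefault(lab, 0.0)

    age = from_age
    while age < to_age - 1e-12:
        dt = min(1.0, to_age - age)
        age += dt
        for labels, rate in groups:
            for lab in labels:
                if lab in state.front_travel:
                    state.front_travel[lab] += rate * dt
            cand = np.isin(state.tissue, labels) & ~state.ossified
            if cand.any():
                travel = np.zeros(len(cand))
                for lab in labels:
                    travel[state.tissue == lab] = state.front_travel.get(lab, 0.0)
                newly = cand & (travel >= state.front_distance)
                state.ossified_since[newly] = age
        # prescribed closures
        if age >= rule.prescribed_closure_age:
            pres = np.isin(state.tissue, PRESCRIBED_CLOSURE_LABELS) & ~state.ossified
            state.ossified_since[pres] = rule.prescribed_closure_age
        # stiffness ramps
        is_bone = np.isin(state.tissue, sorted(BONE_LABELS))
        new_bone = state.ossified & ~is_bone & (state.tissue != "icv")
        state.elastic_modulus[is_bone] += rule.bone_ramp * dt
        state.elastic_modulus[new_bone] += rule.new_bone_ramp * dt
    state.age = to_age
    return state


def closure_fraction(mesh, state: MaterialState, region_label: str) -> float:
    """Ossified volume fraction of a (pre-surgery tissue) region."""
    sel = state.tissue == region_label
    if not sel.any():
        raise ValueError(f"region {region_label!r} is empty")
    vol = mesh.tet_volumes()
    return float(vol[sel & state.ossified].sum() / vol[sel].sum())
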