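"""Load-stepped calvarial growth simulation.

The driver executes the surgical workflow as a sequence of quasi-static
load steps: an in-situ spring release (SAC only), then growth steps in which
the ICV eigenstrain is calibrated to an age--volume schedule, the geometry
is updated to the deformed configuration, ossification fronts advance over
the step's month span, and spring openings/forces are recomputed.  Springs
are removed (force fixed at 0) at the step nearest 9 months of age; SAC runs
end at 36 months, MSC at 60 months.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import fe_core, materials, morphometrics, skull_factory
from .fe_core import ContactSpec, LoadCase
from .materials import MaterialState, OssificationRule, SpringSet
from .morphometrics import MorphometricsReport

__all__ = ["GrowthSchedule", "GrowthStep", "SimulationState", "default_schedule", "run", "update_geometry"]

log = logging.getLogger("calvasim")

# Age (months) -> target ICV (ml) anchor tables.  Anchored at the printed
# pre-operative volume and the printed follow-up targets; intermediate
# anchors follow the printed postoperative predictions.
SAC_VOLUME_ANCHORS = ((4.0, 659.9), (9.0, 829.5), (36.0, 1240.0))
MSC_VOLUME_ANCHORS = ((4.0, 659.9), (9.0, 817.4), (12.0, 1007.0), (36.0, 1240.4), (60.0, 1376.0))
SAC_STEP_AGES = (9.0, 15.0, 22.0, 29.0, 36.0)
MSC_STEP_AGES = (9.0, 12.0, 24.0, 36.0, 48.0, 60.0)


@dataclass
class GrowthStep:
    age: float
    target_icv: float
    events: tuple = ()


@dataclass
class GrowthSchedule:
    technique: str
    start_age: float
    steps: list

    def validate(self) -> None:
        ages = [self.start_age] + [s.age for s in self.steps]
        if np.any(np.diff(ages) <= 0):
            raise ValueError("schedule ages must be strictly increasing")
        vols = [s.target_icv for s in self.steps]
        if np.any(np.diff(vols) < 0):
            raise ValueError("target volumes must be non-decreasing")


def _interp_anchors(anchors, age: float) -> float:
    xs = np.array([a for a, _ in anchors])
    ys = np.array([v for _, v in anchors])
    return float(np.interp(age, xs, ys))


def default_schedule(
    technique: str,
    start_age: float = 4.0,
    step_ages: Optional[tuple] = None,
    volume_anchors: Optional[tuple] = None,
    spring_removal_age: float = 9.0,
) -> GrowthSchedule:
    """The default growth schedule for a technique.

    SAC: five growth steps from (4 mo, 659.9 ml) to (36 mo, 1240 ml) with
    spring removal at the step nearest 9 months.  MSC: six steps ending at
    (60 mo, 1376 ml).  Target volumes interpolate the anchor table.
    """
    if technique not in ("SAC2", "SAC3", "MSC"):
        raise ValueError(f"unknown technique {technique!r}")
    sac = technique != "MSC"
    if step_ages is None:
        step_ages = SAC_STEP_AGES if sac else MSC_STEP_AGES
    if volume_anchors is None:
        volume_anchors = SAC_VOLUME_ANCHORS if sac else MSC_VOLUME_ANCHORS
    steps = [
        GrowthStep(age=a, target_icv=_interp_anchors(volume_anchors, a), events=("report",))
        for a in step_ages
    ]
    if sac:
        k = int(np.argmin([abs(s.age - spring_removal_age) for s in steps]))
        steps[k].events = ("report", "remove_springs")
    sched = GrowthSchedule(technique=technique, start_age=start_age, steps=steps)
    sched.validate()
    return sched


@dataclass
class SimulationState:
    mesh: object
    material: MaterialState
    springs: Optional[SpringSet]
    age: float
    reports: list = field(default_factory=list)
    technique: str = ""
    release_report: Optional[MorphometricsReport] = None
    preop_craniotomy_width: Optional[float] = None
    release_craniotomy_width: Optional[float] = None

    def report_frame(self):
        import pandas as pd

        return pd.DataFrame([r.to_dict() for r in self.reports])


def update_geometry(state: SimulationState, displacement: np.ndarray) -> SimulationState:
    """Advance the reference configuration by a converged displacement."""
    mesh = state.mesh
    new_nodes = mesh.node_coords + displacement
    x = new_nodes[mesh.tets]
    vols = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    if np.any(vols <= 0):
        worst = np.argsort(vols)[:10]
        raise ValueError(
            f"geometry update inverts {int((vols <= 0).sum())} elements; worst: {worst.tolist()}"
        )
    mesh.node_coords = new_nodes
    # cached edge topology is index-based and survives deformation
    if state.springs is not None:
        state.springs.update_from_mesh(new_nodes)
    return state


def _cleanup_penetration(state: SimulationState, contact: ContactSpec) -> None:
    """Remove residual ICV/inner-table interpenetration from the reference.

    Penalty contact leaves up to the penetration tolerance baked into each
    updated geometry; left alone it accumulates over sub-steps until the
    penalty loop destabilises.  Penetrating ICV surface nodes are projected
    back through the master facet (the mesh-repair step between intervals).
    """
    mesh = state.mesh
    cs = fe_core.build_contact_state(mesh, contact)
    if cs is None:
        return
    pen = cs.gap0 < -1e-9
    if pen.any():
        corr = np.zeros_like(mesh.node_coords)
        corr[cs.slave_nodes[pen]] = (-cs.gap0[pen])[:, None] * cs.normals[pen]
        scale = 1.0
        for _ in range(3):
            trial = mesh.node_coords + scale * corr
            x = trial[mesh.tets]
            if np.all(np.linalg.det(x[:, 1:] - x[:, :1]) > 0):
                mesh.node_coords = trial
                break
            scale *= 0.5
    # whatever projection could not remove becomes a contact reference
    # offset (adjust-to-touch), so the penalty never fights baked-in
    # interpenetration it cannot undo
    cs2 = fe_core.build_contact_state(mesh, contact)
    resid = np.minimum(cs2.gap0, 0.0)
    if (resid < -1e-9).any():
        bias_nodes = mesh.meta.get("contact_bias_nodes")
        if bias_nodes is not None and np.array_equal(bias_nodes, cs2.slave_nodes):
            mesh.meta["contact_bias_values"] = mesh.meta["contact_bias_values"] + resid
        else:
            mesh.meta["contact_bias_nodes"] = cs2.slave_nodes
            mesh.meta["contact_bias_values"] = resid


def _make_report(state, contact_spec, solve_result, closure_labels=("craniotomy",)) -> MorphometricsReport:
    rep = morphometrics.measure(state.mesh, age=state.age)
    if state.springs is not None:
        for s in state.springs:
            if not s.removed:
                rep.spring_openings[s.position_mm] = morphometrics.spring_opening(s, state.mesh)
                rep.spring_forces[s.position_mm] = s.force
    if solve_result is not None and solve_result.contact is not None:
        pmap = fe_core.contact_pressure_map(state.mesh, solve_result, contact_spec)
        rep.contact_pressure = morphometrics.pressure_summary(state.mesh, pmap)
    for lab in closure_labels:
        if (state.material.tissue == lab).any():
            rep.closure[lab] = materials.closure_fraction(state.mesh, state.material, lab)
    return rep


def run(
    mesh,
    plan: skull_factory.SurgeryPlan,
    schedule: Optional[GrowthSchedule] = None,
    contact: Optional[ContactSpec] = None,
    rule: Optional[OssificationRule] = None,
    springs: Optional[SpringSet] = None,
    order: int = 2,
    snapshot_hook=None,
    max_volume_increment: float = 0.12,
) -> SimulationState:
    """Execute the full post-operative growth simulation.

    ``mesh`` must already carry the virtual surgery of ``plan``.  Returns the
    final state with one morphometrics report per step (plus the release
    report for SAC).  ``snapshot_hook(state, tag)`` is called after release
    and after every step, for file output.
    """
    if schedule is None:
        schedule = default_schedule(plan.technique)
    if schedule.technique != plan.technique:
        raise ValueError(
            f"schedule technique {schedule.technique!r} != plan technique {plan.technique!r}"
        )
    schedule.validate()
    contact = contact if contact is not None else ContactSpec()
    rule = rule if rule is not None else OssificationRule()
    sac = plan.technique != "MSC"
    state = SimulationState(
        mesh=mesh.copy(),
        material=materials.default_material_state(mesh, age=schedule.start_age),
        springs=None,
        age=schedule.start_age,
        technique=plan.technique,
    )
    if sac:
        state.springs = springs if springs is not None else skull_factory.place_springs(state.mesh, plan)

    closure_labels = ["craniotomy", "metopic_suture", "anterior_fontanelle"]

    if sac:
        t0 = time.time()
        state.preop_craniotomy_width = morphometrics.craniotomy_width(state.mesh)
        lc = LoadCase(eigenstrain=0.0, springs=state.springs)
        res = fe_core.solve_static(state.mesh, state.material, lc, contact, order=order)
        update_geometry(state, res.displacement)
        state.release_craniotomy_width = morphometrics.craniotomy_width(state.mesh)
        state.release_report = _make_report(state, contact, res, closure_labels)
        log.info(
            "release: %.1fs, %d iterations, openings %s",
            time.time() - t0,
            res.iterations,
            {p: round(d, 2) for p, d, _ in res.spring_forces},
        )
        if snapshot_hook:
            snapshot_hook(state, "release")

    contact_warm: dict = {}
    eps_hint = None
    prev_gain = None
    lc = LoadCase()
    inc = max_volume_increment
    for k, step in enumerate(schedule.steps):
        t0 = time.time()
        # split large volume targets into geometric sub-increments so each
        # linear solve stays in the small-strain regime; the geometry (and
        # spring state) is updated after every sub-increment
        res = None
        while True:
            current = state.mesh.icv_volume_ml()
            if current >= step.target_icv * (1 - 0.005):
                break
            sub_target = min(step.target_icv, current * (1.0 + inc))
            if prev_gain is not None and prev_gain > 0:
                eps_hint = lc.eigenstrain * (sub_target - current) / prev_gain
            t_sub = time.time()
            for attempt in range(4):
                final_sub = sub_target >= step.target_icv * (1 - 1e-12)
                lc, res = fe_core.calibrate_eigenstrain(
                    state.mesh,
                    state.material,
                    contact,
                    sub_target,
                    springs=state.springs if sac else None,
                    order=order,
                    eps0=eps_hint,
                    rel_tol=0.005 if final_sub else 0.03,
                    warm=contact_warm,
                )
                try:
                    update_geometry(state, res.displacement)
                    _cleanup_penetration(state, contact)
                    break
                except ValueError:
                    # too large an increment distorts elements: halve and retry
                    if attempt == 3:
                        raise
                    sub_target = current + 0.5 * (sub_target - current)
                    eps_hint = lc.eigenstrain * 0.5
                    inc = max(inc * 0.6, 0.02)  # stay conservative from here on
                    log.info("  inversion: retry with sub-target %.1f ml", sub_target)
            prev_gain = sub_target - current
            inc = min(inc * 1.3, max_volume_increment)  # recover after clean substeps
            log.info(
                "  substep -> %.1f ml (eps %.4f, %d it, %.0fs)",
                sub_target, lc.eigenstrain, res.iterations, time.time() - t_sub,
            )
        state.material = materials.advance_ossification(
            state.mesh, state.material, rule, state.age, step.age
        )
        state.age = step.age
        achieved = state.mesh.icv_volume_ml()
        log.info(
            "step %d (age %.0f mo): eps=%.4f, ICV %.1f ml (target %.1f), %.1fs",
            k,
            step.age,
            lc.eigenstrain,
            achieved,
            step.target_icv,
            time.time() - t0,
        )
        if "report" in step.events:
            state.reports.append(_make_report(state, contact, res, closure_labels))
        if "remove_springs" in step.events and state.springs is not None:
            state.springs.remove_all()
            log.info("springs removed at %.0f months", step.age)
        if snapshot_hook:
            snapshot_hook(state, f"age{step.age:g}")
    return state
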