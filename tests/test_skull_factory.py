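import warnings

import numpy as np
import pytest

from calvasim import build_calvaria, SurgeryPlan, apply_surgery, place_springs
from calvasim.materials import MATERIAL_TABLE
from calvasim.morphometrics import measure

from conftest import COARSE


def test_generator_is_bit_deterministic():
    a = build_calvaria(**COARSE)
    b = build_calvaria(**COARSE)
    assert np.array_equal(a.node_coords, b.node_coords)
    assert np.array_equal(a.tets, b.tets)
    assert np.array_equal(a.region_labels, b.region_labels)


def test_jittered_generator_seed_behaviour():
    a = build_calvaria(jitter=0.1, seed=3, **COARSE)
    b = build_calvaria(jitter=0.1, seed=3, **COARSE)
    c = build_calvaria(jitter=0.1, seed=4, **COARSE)
    assert np.array_equal(a.node_coords, b.node_coords)
    assert not np.array_equal(a.node_coords, c.node_coords)
    a.validate()


def test_mesh_invariants(coarse_calvaria, default_calvaria):
    m = coarse_calvaria
    m.validate()
    assert (m.tet_volumes() > 0).all()
    assert set(np.unique(m.region_labels)) <= set(MATERIAL_TABLE)
    # the default build sits inside the desk-scale element window
    assert 5_000 <= len(default_calvaria.tets) <= 500_000


def test_default_dimensions_match_preoperative_model(default_calvaria):
    rep = measure(default_calvaria)
    assert rep.length == pytest.approx(137.2, rel=0.02)
    assert rep.width == pytest.approx(108.1, rel=0.02)
    assert rep.circumference == pytest.approx(430.6, rel=0.02)
    assert rep.icv_volume == pytest.approx(659.9, rel=0.02)


def test_spherical_parameters_give_round_skull():
    m = build_calvaria(
        length=120.0, width=120.0, circumference=None, icv_volume_ml=500.0,
        superellipse_exponent=2.0, **COARSE,
    )
    rep = measure(m)
    assert rep.length == pytest.approx(rep.width, rel=1e-4)
    assert rep.cephalic_index == pytest.approx(100.0, abs=0.02)


def test_ellipsoid_volume_against_closed_form():
    """With a full elliptical profile the dome height solved by the generator
    must match the closed-form ellipsoid volume within discretization error."""
    m = build_calvaria(
        length=140.0, width=110.0, circumference=None, icv_volume_ml=700.0,
        superellipse_exponent=2.0, base_flatten=1.0,
        shell_nlat=24, shell_nlon=48, icv_nlat=16, icv_nlon=32,
    )
    a, b = m.meta["a_inner"], m.meta["b_inner"]
    c_analytic = 700.0e3 / (4.0 / 3.0 * np.pi * a * b)
    assert m.meta["c_inner"] == pytest.approx(c_analytic, rel=0.05)
    assert m.icv_volume_ml() == pytest.approx(700.0, rel=1e-6)


def test_dimension_scaling_is_monotone():
    lengths, widths = [], []
    for L, W in [(120.0, 95.0), (137.0, 108.0), (152.0, 120.0)]:
        m = build_calvaria(
            length=L, width=W, circumference=None, superellipse_exponent=3.0, **COARSE
        )
        rep = measure(m)
        lengths.append(rep.length)
        widths.append(rep.width)
    assert np.all(np.diff(lengths) > 0)
    assert np.all(np.diff(widths) > 0)


def test_degenerate_parameters_raise():
    with pytest.raises(ValueError):
        build_calvaria(thickness=0.0)
    with pytest.raises(ValueError):
        build_calvaria(suture_width=30.0)
    with pytest.raises(ValueError):
        build_calvaria(shell_nlat=8, shell_nlon=16, icv_nlat=8, icv_nlon=16)  # too few elements


def test_sac_surgery_relabels_midline_strip(coarse_calvaria):
    plan = SurgeryPlan("SAC2")
    m = apply_surgery(coarse_calvaria, plan)
    strip = m.region_labels == "craniotomy"
    assert strip.any()
    # only former parietal bone / fused sagittal becomes craniotomy
    prev = coarse_calvaria.region_labels[strip]
    assert set(prev.tolist()) <= {"parietal_L", "parietal_R", "fused_sagittal"}
    # strip width within one element size of the plan
    c = m.element_centroids()[strip]
    assert np.abs(c[:, 0]).max() <= plan.craniotomy_width / 2 + m.element_size()
    # anchors tagged for both springs
    for k in range(2):
        assert f"spring_anchor_{k}_L" in m.node_sets
        assert f"spring_anchor_{k}_R" in m.node_sets
    m.validate()


def test_msc_surgery_wide_strip_no_anchors(coarse_calvaria):
    plan = SurgeryPlan("MSC")
    m = apply_surgery(coarse_calvaria, plan)
    c = m.element_centroids()[m.region_labels == "craniotomy"]
    assert c[:, 0].max() <= 25.0 + m.element_size()
    assert c[:, 0].max() > 15.0  # genuinely wide
    assert not any(k.startswith("spring_anchor") for k in m.node_sets)


def test_zero_extent_surgery_warns_and_leaves_mesh(coarse_calvaria):
    plan = SurgeryPlan("SAC2", extent=(10.0, 10.0))
    with pytest.warns(UserWarning):
        m = apply_surgery(coarse_calvaria, plan)
    assert not (m.region_labels == "craniotomy").any()
    assert np.array_equal(m.region_labels, coarse_calvaria.region_labels)


@pytest.mark.parametrize("technique,n", [("SAC2", 2), ("SAC3", 3)])
def test_spring_placement(default_calvaria, technique, n):
    plan = SurgeryPlan(technique)
    m = apply_surgery(default_calvaria, plan)
    springs = place_springs(m, plan)
    assert len(springs) == n
    for s in springs:
        assert s.distance == pytest.approx(15.0, abs=m.element_size())
        assert s.free_length == 100.0
        assert s.stiffness == pytest.approx(8.0 / 85.0)


def test_msc_has_no_springs(coarse_calvaria):
    plan = SurgeryPlan("MSC")
    m = apply_surgery(coarse_calvaria, plan)
    with pytest.raises(ValueError, match="no springs"):
        place_springs(m, plan)


def test_spring_position_beyond_lambdoid_raises(coarse_calvaria):
    plan = SurgeryPlan("SAC2", spring_positions=(40.0, 130.0))
    with pytest.raises(ValueError, match="130"):
        apply_surgery(coarse_calvaria, plan)
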