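import numpy as np
import pytest

from calvasim import (
    SurgeryPlan,
    apply_surgery,
    advance_ossification,
    closure_fraction,
    default_material_state,
    spring_force,
    spring_stiffness,
)
from calvasim.materials import OssificationRule, Spring
from calvasim.io_cli import make_toy_fixture


@pytest.fixture(scope="module")
def surgical_state(coarse_calvaria):
    mesh = apply_surgery(coarse_calvaria, SurgeryPlan("SAC2"))
    return mesh, default_material_state(mesh)


@pytest.mark.parametrize(
    "label,E,nu",
    [
        ("parietal_L", 421.0, 0.3),
        ("fused_sagittal", 421.0, 0.3),
        ("coronal_suture", 30.0, 0.3),
        ("anterior_fontanelle", 30.0, 0.3),
        ("craniotomy", 0.3, 0.1),
        ("icv", 10.0, 0.1),
    ],
)
def test_material_table_assignment(surgical_state, label, E, nu):
    mesh, state = surgical_state
    sel = state.tissue == label
    assert sel.any()
    assert np.all(state.elastic_modulus[sel] == E)
    assert np.all(state.poisson_ratio[sel] == nu)


def test_unknown_label_raises(coarse_calvaria):
    m = coarse_calvaria.copy()
    m.region_labels = m.region_labels.copy()
    m.region_labels[0] = "mystery_tissue"
    with pytest.raises(KeyError, match="mystery_tissue"):
        default_material_state(m)


def test_spring_stiffness_from_crimp_measurement():
    assert spring_stiffness(8.0, 100.0, 15.0) == pytest.approx(8.0 / 85.0)
    assert spring_stiffness(8.0, 100.0, 99.0) == pytest.approx(8.0)
    with pytest.raises(ValueError):
        spring_stiffness(8.0, 100.0, 100.0)
    with pytest.raises(ValueError):
        spring_stiffness(-1.0, 100.0, 15.0)


def test_spring_force_hooke_law():
    s = Spring(anchors_L=np.array([0]), anchors_R=np.array([1]), stiffness=8.0 / 85.0)
    s.distance = 15.0
    assert spring_force(s) == pytest.approx(8.0, abs=1e-9)
    s.distance = 100.0
    assert spring_force(s) == 0.0
    s.active = False
    assert spring_force(s) == 0.0
    s.active = True
    s.distance = 120.0  # over-opened
    assert spring_force(s) == 0.0  # clamped by default
    s.clamp_compression = False
    assert spring_force(s) < 0.0


def test_strip_suture_closes_at_front_rate():
    """A 2 mm strip healing bilaterally at 0.2 mm/month closes in 5 months."""
    mesh, info = make_toy_fixture("strip_suture", resolution=0.5)
    state = default_material_state(mesh, age=0.0)
    rule = OssificationRule(suture_front_rate=0.2)
    s3 = advance_ossification(mesh, state, rule, 0.0, 3.0)
    assert closure_fraction(mesh, s3, "coronal_suture") < 1.0
    s5 = advance_ossification(mesh, state, rule, 0.0, 5.0 + 1e-9)
    assert closure_fraction(mesh, s5, "coronal_suture") == pytest.approx(1.0)


def test_front_rate_recovery_within_element_size():
    """Measured monthly front advance matches the configured rate."""
    mesh, _ = make_toy_fixture("strip_suture", resolution=0.5)
    state = default_material_state(mesh, age=0.0)
    rule = OssificationRule(suture_front_rate=0.3)
    h = mesh.element_size()
    cent = mesh.element_centroids()
    for months in (1.0, 2.0, 3.0):
        s = advance_ossification(mesh, state, rule, 0.0, months)
        oss = s.ossified & (s.tissue == "coronal_suture")
        if not oss.any():
            advance = 0.0
        else:
            advance = 1.0 - np.abs(cent[oss][:, 0]).min()  # from the +-1 mm interface
        assert advance == pytest.approx(rule.suture_front_rate * months, abs=h)


def test_ossification_is_order_independent():
    mesh, _ = make_toy_fixture("strip_suture", resolution=0.5)
    state = default_material_state(mesh, age=0.0)
    rule = OssificationRule(suture_front_rate=0.2)
    one_call = advance_ossification(mesh, state, rule, 0.0, 4.0)
    stepped = state
    for m in range(4):
        stepped = advance_ossification(mesh, stepped, rule, float(m), float(m + 1))
    assert np.array_equal(one_call.ossified, stepped.ossified)
    assert np.allclose(one_call.elastic_modulus, stepped.elastic_modulus)


def test_zero_interval_is_identity():
    mesh, _ = make_toy_fixture("strip_suture", resolution=0.5)
    state = default_material_state(mesh, age=0.0)
    out = advance_ossification(mesh, state, OssificationRule(), 2.0, 2.0)
    assert np.array_equal(out.elastic_modulus, state.elastic_modulus)
    assert np.array_equal(out.ossified, state.ossified)
    with pytest.raises(ValueError):
        advance_ossification(mesh, state, OssificationRule(), 2.0, 1.0)


def test_bone_modulus_ramp_arithmetic():
    mesh, _ = make_toy_fixture("strip_suture", resolution=0.5)
    state = default_material_state(mesh, age=0.0)
    out = advance_ossification(mesh, state, OssificationRule(), 0.0, 5.0)
    bone = out.tissue == "parietal_L"
    assert np.all(out.elastic_modulus[bone] == pytest.approx(421.0 + 5 * 125.0))


def test_stiffening_is_monotone_in_time(surgical_state):
    mesh, state = surgical_state
    rule = OssificationRule()
    prev = state
    for a, b in [(4.0, 6.5), (6.5, 9.0), (9.0, 20.0), (20.0, 30.0)]:
        cur = advance_ossification(mesh, prev, rule, a, b)
        assert np.all(cur.elastic_modulus >= prev.elastic_modulus - 1e-12)
        assert not cur.ossified[cur.tissue == "icv"].any()
        prev = cur


def test_prescribed_closures_complete_at_24_months(surgical_state):
    mesh, state = surgical_state
    out = advance_ossification(mesh, state, OssificationRule(), 4.0, 24.0)
    assert closure_fraction(mesh, out, "metopic_suture") == pytest.approx(1.0)
    assert closure_fraction(mesh, out, "anterior_fontanelle") == pytest.approx(1.0)
    before = advance_ossification(mesh, state, OssificationRule(), 4.0, 20.0)
    assert closure_fraction(mesh, before, "metopic_suture") < 1.0


def test_closure_fraction_edges(surgical_state):
    mesh, state = surgical_state
    assert closure_fraction(mesh, state, "craniotomy") == 0.0
    assert closure_fraction(mesh, state, "parietal_L") == 1.0
    with pytest.raises(ValueError):
        closure_fraction(mesh, state, "absent_region")
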