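import numpy as np
import pytest

from calvasim import build_calvaria, SurgeryPlan, apply_surgery, place_springs


COARSE = dict(shell_nlat=16, shell_nlon=32, icv_nlat=8, icv_nlon=16)


@pytest.fixture(scope="session")
def coarse_calvaria():
    """Small, fast calvaria for unit tests (~5k elements)."""
    return build_calvaria(**COARSE)


@pytest.fixture(scope="session")
def default_calvaria():
    """The default desk-scale calvaria (the study's pre-operative model)."""
    return build_calvaria()


@pytest.fixture(scope="session")
def sac2_setup(default_calvaria):
    plan = SurgeryPlan("SAC2")
    mesh = apply_surgery(default_calvaria, plan)
    springs = place_springs(mesh, plan)
    return mesh, plan, springs


@pytest.fixture(scope="session")
def sac2_run(default_calvaria):
    """Full default SAC2 growth simulation (release -> 36 months)."""
    from calvasim.growth_driver import run

    plan = SurgeryPlan("SAC2")
    mesh = apply_surgery(default_calvaria, plan)
    return run(mesh, plan)


@pytest.fixture(scope="session")
def msc_run(default_calvaria):
    """Full default MSC growth simulation (-> 60 months)."""
    from calvasim.growth_driver import run

    plan = SurgeryPlan("MSC")
    mesh = apply_surgery(default_calvaria, plan)
    return run(mesh, plan)
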