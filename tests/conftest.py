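"""Shared fixtures: geometry, rasterized masks, and solved flow histories.

The arch flow solves are the expensive pieces (tens of seconds each), so
they are session-scoped and shared between the solver, transport, ensemble,
and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from emboflow.flow_solver import SolverConfig, run_cycles
from emboflow.geometry import build_arch, rasterize
from emboflow.hemodynamics import BloodProperties, make_condition

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blood():
    return BloodProperties()


@pytest.fixture(scope="session")
def case1_geometry():
    return build_arch("I")


@pytest.fixture(scope="session")
def arch_mask(case1_geometry):
    return rasterize(case1_geometry, case1_geometry.D_AA / 32)


@pytest.fixture(scope="session")
def solver_config():
    return SolverConfig()


@pytest.fixture(scope="session")
def normal_condition(blood, case1_geometry):
    return make_condition("normal", blood=blood, D=case1_geometry.D_AA)


@pytest.fixture(scope="session")
def af_condition(blood, case1_geometry):
    return make_condition("af", blood=blood, D=case1_geometry.D_AA)


@pytest.fixture(scope="session")
def normal_history(normal_condition, arch_mask, solver_config):
    return run_cycles(normal_condition, arch_mask, solver_config)


@pytest.fixture(scope="session")
def af_history(af_condition, arch_mask, solver_config):
    return run_cycles(af_condition, arch_mask, solver_config)
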