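import numpy as np
import pytest

import perifem as pf
from perifem import fem as F
from perifem import meshing as M
from perifem import geometry as G
from perifem import stress_risk as SR
from perifem.study import StudyRunner, p1_sweep_scenarios


@pytest.fixture(scope="session")
def catalogue():
    return pf.implant_catalogue()


@pytest.fixture(scope="session")
def scenario8_p1(catalogue):
    return pf.build_scenario(catalogue["8"], "P1")


@pytest.fixture(scope="session")
def mesh8_coarse(scenario8_p1):
    size = M.make_size_field(3.6, h0_ratio=0.3, hi_ratio=0.3)
    return M.mesh_scenario(scenario8_p1, size)


@pytest.fixture(scope="session")
def solved8(mesh8_coarse):
    system, u, sig = F.solve_scenario(mesh8_coarse)
    return system, u, sig


@pytest.fixture(scope="session")
def regions8(mesh8_coarse, scenario8_p1, solved8):
    _, _, sig = solved8
    return SR.build_control_regions(mesh8_coarse, scenario8_p1, sig)


@pytest.fixture(scope="session")
def reduced_scenario8(catalogue):
    """Implant 8 at P1 on a shortened (29 mm) segment for convergence runs."""
    bone = G.BoneSegmentSpec(mesiodistal_length_mm=29.0)
    return pf.build_scenario(catalogue["8"], "P1", bone_spec=bone)


@pytest.fixture(scope="session")
def convergence_walk(reduced_scenario8):
    """Two-level nested-refinement convergence run at the mesh-acceptance
    thresholds (5 % energy norm, 0.5 % displacement change)."""
    from perifem.recovery import converge_mesh
    return converge_mesh(reduced_scenario8, (0.5, 0.25))


@pytest.fixture(scope="session")
def test_runner():
    """Shared desk-scale study runner (results cached across tests)."""
    return StudyRunner(hi_ratio=0.2, h0_ratio=0.2)


@pytest.fixture(scope="session")
def p1_study(test_runner):
    return test_runner.run_study(p1_sweep_scenarios())


def rng(seed=0):
    return np.random.default_rng(seed)
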