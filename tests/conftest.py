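"""Shared fixtures: materials, random deformation states, meshes and one
reference flexion/extension run reused across solver, analysis and
acceptance tests."""

import numpy as np
import pytest

from discfem import constitutive as cm
from discfem import geometry as geo
from discfem import solver as sv

KPA = 1.0e3


@pytest.fixture(scope="session")
def np_mat():
    return cm.load_material("np_table1")


@pytest.fixture(scope="session")
def af_mat():
    return cm.load_material("af_table1")


@pytest.fixture(scope="session")
def np_mat_kpa():
    """Nucleus material with the printed numbers read as kPa (unit-agnostic
    arithmetic checks)."""
    return cm.NPMaterial(b10=0.12 * KPA, b01=0.03 * KPA, k=29.9 * KPA)


@pytest.fixture(scope="session")
def af_mat_kpa():
    return cm.AFMaterial(c10=0.18 * KPA, c01=0.045 * KPA, a1=2.0 * KPA,
                         a2=100.0, k=4.35 * KPA)


@pytest.fixture(scope="session")
def fibers30():
    return cm.FiberPair.from_angle(30.0)


def random_deformations(n, amplitude=0.3, seed=0, min_det=0.25):
    """Random admissible deformation gradients (det F bounded away from 0)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(3) + amplitude * rng.uniform(-1.0, 1.0, size=(n, 3, 3))
        out.extend(F[np.linalg.det(F) > min_det])
    return np.asarray(out[:n])


@pytest.fixture(scope="session")
def random_states():
    return random_deformations(100, seed=42)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Non-degenerated segment at 4 mm nominal size (fast solver tests)."""
    return geo.generate_segment(geo.SegmentSpec.preset("none", element_size=4.0),
                                seed=1)


@pytest.fixture(scope="session")
def table1():
    return sv.DiscMaterials.table1()


@pytest.fixture(scope="session")
def audit_mesh():
    """Non-degenerated segment at 3 mm for the wave-speed audit runs."""
    return geo.generate_segment(geo.SegmentSpec.preset("none", element_size=3.0),
                                seed=1)


def run_case(mesh, mats, name, **kwargs):
    case = sv.LoadCase.standard(name, **kwargs)
    return sv.run_explicit(mesh, mats, case)


@pytest.fixture(scope="session")
def flexion_run(audit_mesh, table1):
    """Peak 5 Nm flexion of the non-degenerated synthetic segment."""
    return run_case(audit_mesh, table1, "flexion")


@pytest.fixture(scope="session")
def extension_run(audit_mesh, table1):
    return run_case(audit_mesh, table1, "extension")


@pytest.fixture(scope="session")
def coarse_flexion_run(coarse_mesh, table1):
    return run_case(coarse_mesh, table1, "flexion")
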