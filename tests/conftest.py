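import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellimp import build_layout, generate_mesh, solve_field
from cellimp import materials

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hela_tables():
    return materials.load_hela_tables()


@pytest.fixture(scope="session")
def kappa_pbs_100k():
    return materials.complex_admittivity(materials.PBS, 1e5)


def solve_device(shape, f, V, with_cell=True, resolution=1e-6, overrides=None,
                 tables=None):
    """Convenience end-to-end solve used across test modules."""
    layout = build_layout(shape, overrides or {})
    mesh = generate_mesh(layout, resolution)
    kp = materials.complex_admittivity(materials.PBS, f)
    if with_cell:
        sigma_tab, eps_tab = tables or materials.load_hela_tables()
        props = materials.cell_properties(sigma_tab, eps_tab, f, V)
        kc = materials.complex_admittivity(props, f)
    else:
        kc = kp
    return solve_field(mesh, {0: kp, 1: kc}, V=V, f=f)


@pytest.fixture(scope="session")
def parallel_cell_solution(hela_tables):
    """Parallel device, 0.1 V, 100 kHz, with cell, 1 um mesh."""
    return solve_device("parallel", 1e5, 0.1, tables=hela_tables)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151604)
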