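import numpy as np
import pytest

from modemorph import (
    SimulationConfig,
    SurfaceMap,
    TemplateSpec,
    compute_eigenmodes,
    generate_cohort,
    make_icosphere,
)


@pytest.fixture(scope="session")
def ico1():
    """42-vertex unit icosphere (small enough for dense oracles)."""
    return make_icosphere(subdivisions=1, radius=1.0)


@pytest.fixture(scope="session")
def ico3():
    """642-vertex unit icosphere, the workhorse analysis mesh."""
    return make_icosphere(subdivisions=3, radius=1.0)


@pytest.fixture(scope="session")
def basis_ico3(ico3):
    """50-mode basis on the unit icosphere s=3."""
    return compute_eigenmodes(ico3, n_modes=50)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort for fast end-to-end tests."""
    cfg = SimulationConfig(n_hc=6, n_presymptomatic=4, n_symptomatic=8, seed=42)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


def full_map(mesh, values, name=None):
    return SurfaceMap.full(mesh, values, name=name)


@pytest.fixture()
def tetra_off_text():
    return (
        "OFF\n"
        "4 4 6\n"
        "1 1 1\n"
        "-1 -1 1\n"
        "-1 1 -1\n"
        "1 -1 -1\n"
        "3 0 1 2\n"
        "3 0 3 1\n"
        "3 0 2 3\n"
        "3 1 3 2\n"
    )
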