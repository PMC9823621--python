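import numpy as np
import pytest

from frustulight.geometry import (GeometryScene, build_analytic_component,
                                  build_longitudinal_cs, rasterize)
from frustulight.params import CrossSectionSpec, OpticalConstants, ValveParameters
from frustulight.solver import SimulationConfig, solve


@pytest.fixture(scope="session")
def valve_params():
    return ValveParameters()


@pytest.fixture(scope="session")
def small_config():
    """Small solver domain for fast validation runs."""
    return SimulationConfig(box_width_x=10.0, box_height_y=6.0,
                            source_width=None, res_factor=15.0)


@pytest.fixture(scope="session")
def small_box():
    return (0.0, -3.0, 10.0, 3.0)


def solve_scene(scene, lam_nm, config, box):
    grid = rasterize(scene, config.resolution_for(lam_nm, scene.optics.n_v),
                     box=box, lam_min_nm=lam_nm)
    return solve(grid, lam_nm, config)


@pytest.fixture(scope="session")
def homogeneous_field(small_config, small_box):
    scene = GeometryScene([], OpticalConstants(), "homogeneous", {})
    return solve_scene(scene, 500.0, small_config, small_box)


@pytest.fixture(scope="session")
def slab_scene_air():
    """Laterally uniform valve-face slab (spans the box through the PML)."""
    return build_analytic_component("slab", {"L": 30.0, "D": 0.17},
                                    OpticalConstants(1.46, 1.00), face_x=4.0)


@pytest.fixture(scope="session")
def cs_long5(valve_params):
    return build_longitudinal_cs(valve_params,
                                 CrossSectionSpec(family="long", index="5"))
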