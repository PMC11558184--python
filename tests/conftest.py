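"""Shared fixtures: small chambers and simulated clots, generated at test time.

Study-scale chambers (7.3 x 3 x 20 mm at 20 um voxels) are large; most tests
run on geometrically faithful but shorter/flatter chambers at 40 um voxels so
the whole suite stays fast.  Tests that check voxel-resolution convergence
build their own finer grids.
"""

from __future__ import annotations

import numpy as np
import pytest

from fiberclot import (
    ChamberSpec,
    ClotSimParams,
    FlowCondition,
    simulate_clot,
    voxelize_chamber,
)


@pytest.fixture(scope="session")
def small_spec() -> ChamberSpec:
    """Full-width chamber, shortened path and height, for fast simulation."""
    return ChamberSpec(path_length=10.0, height=1.5, packing_density=0.50)


@pytest.fixture(scope="session")
def small_solid(small_spec):
    return voxelize_chamber(small_spec, voxel_size=40.0)


@pytest.fixture(scope="session")
def small_condition(small_spec) -> FlowCondition:
    return FlowCondition.for_velocity(20.0, small_spec)


@pytest.fixture(scope="session")
def small_clot(small_solid, small_spec, small_condition):
    params = ClotSimParams(steps=15, seed=7)
    return simulate_clot(small_solid, small_spec, small_condition, params)


@pytest.fixture(scope="session")
def render_spec() -> ChamberSpec:
    """Short full-height chamber used for grayscale rendering tests (20 um)."""
    return ChamberSpec(path_length=5.0, height=3.0, packing_density=0.50)


@pytest.fixture(scope="session")
def render_solid(render_spec):
    return voxelize_chamber(render_spec, voxel_size=20.0)


@pytest.fixture(scope="session")
def render_clot(render_solid, render_spec):
    cond = FlowCondition.for_velocity(20.0, render_spec)
    return simulate_clot(render_solid, render_spec, cond, ClotSimParams(steps=20, seed=1))
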