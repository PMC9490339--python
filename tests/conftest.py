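import numpy as np
import pytest

from membud import (
    MechanicalParameters,
    SolverConfig,
    build_mesh,
    curvature_sweep,
    flat_state,
    generate_dataset,
    solve_equilibrium,
)


@pytest.fixture(scope="session")
def fast_cfg():
    """Coarse but converging solver settings used throughout the suite."""
    return SolverConfig(mesh_points=200)


@pytest.fixture(scope="session")
def bud_params():
    """A low-tension, mid-size patch that buds readily."""
    return MechanicalParameters(patch_radius=100.0, edge_tension=0.02,
                                patch_pressure=1.0e-4)


@pytest.fixture(scope="session")
def bud_sweep(bud_params, fast_cfg):
    """A full ascending+descending sweep of the budding parameter set."""
    records = curvature_sweep(bud_params, solver_cfg=fast_cfg)
    assert records, "fixture sweep produced no convergent records"
    return records


@pytest.fixture(scope="session")
def flat_solution(fast_cfg):
    params = MechanicalParameters(patch_radius=50.0, edge_tension=0.05)
    mesh = build_mesh(params.total_area, fast_cfg.mesh_points)[1:]
    state = solve_equilibrium(params, 0.0, flat_state(mesh, params.edge_tension),
                              fast_cfg)
    return params, state

@pytest.fixture(scope="session")
def tiny_pressure_table():
    """A small regenerated pressure-space dataset shared by the ML tests."""
    return generate_dataset("pressure", 12, seed=42,
                            solver_cfg=SolverConfig(mesh_points=150))
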