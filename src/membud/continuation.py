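"""Spontaneous-curvature continuation: squared mesh, ascending/descending sweeps.

The equilibrium branch is traced by slowly stepping the patch spontaneous
curvature: starting from the flat membrane at C = 0, C is increased in
fixed steps, each solve warm-started from the previous converged state,
until the solver first fails or C reaches its cap. Because the model
exhibits snapthrough instabilities, the last ascending solution then seeds
a descending sweep back toward C = 0; states on the upper branch at the
same C can differ from the ascending ones (hysteresis), and both are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from membud.parameters import MechanicalParameters, InvalidParameterError
from membud.mechanics import (
    MembraneState,
    NonConvergence,
    SolverConfig,
    flat_state,
    solve_equilibrium,
)

__all__ = ["ContinuationRecord", "build_mesh", "curvature_sweep",
           "DEFAULT_C_STEP", "DEFAULT_C_MAX"]

DEFAULT_C_STEP = 0.0007  # 1/nm
DEFAULT_C_MAX = 0.07     # 1/nm


@dataclass(frozen=True)
class ContinuationRecord:
    """One converged solve of a sweep: its direction, C value and state."""

    direction: str  # "ascending" | "descending"
    C_value: float
    state: MembraneState
    step_index: int


def build_mesh(A_total: float, n_points: int) -> np.ndarray:
    """Squared mesh on [0, A_total]: node i = (i/(n-1))^2 * A_total.

    Squaring a uniform unit mesh concentrates nodes near the pole, where
    the patch sits and the shape varies fastest. The first node is 0 and
    is dropped by the sweep, which imposes the inner boundary at the first
    interior node.
    """
    if n_points < 10:
        raise InvalidParameterError("n_points must be >= 10")
    if A_total <= 0:
        raise InvalidParameterError("A_total must be positive")
    u = np.linspace(0.0, 1.0, int(n_points))
    return u * u * A_total


def _interp_state(state: MembraneState, mesh: np.ndarray) -> MembraneState:
    """Re-evaluate a state on `mesh` by linear interpolation (warm starts)."""
    if state.mesh.shape == mesh.shape and np.allclose(state.mesh, mesh):
        return state
    cols = [np.interp(mesh, state.mesh, v) for v in
            (state.r, state.z, state.psi, state.H, state.L, state.lam)]
    return MembraneState(mesh=mesh, r=cols[0], z=cols[1], psi=cols[2],
                         H=cols[3], L=cols[4], lam=cols[5],
                         converged=state.converged, params=state.params,
                         C_value=state.C_value,
                         warm_start_C=state.warm_start_C)


def curvature_sweep(
    params: MechanicalParameters,
    step: float = DEFAULT_C_STEP,
    C_max: float = DEFAULT_C_MAX,
    solver_cfg: Optional[SolverConfig] = None,
) -> List[ContinuationRecord]:
    """Run the ascending-then-descending curvature continuation.

    Ascending: solve at C = 0, step, 2*step, ... warm-starting each solve
    from the previous converged state, stopping at the first failure or
    once C exceeds ``C_max`` (at most ceil(C_max/step) steps above zero).
    Descending: restart from the last ascending converged state and lower
    C by the same step down to 0 inclusive, again stopping on the first
    failure. Every converged state of either phase becomes one record;
    downstream consumers pool them without distinction.
    """
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    cfg = solver_cfg or SolverConfig()
    mesh = build_mesh(params.total_area, cfg.mesh_points)[1:]

    records: List[ContinuationRecord] = []
    guess = flat_state(mesh, params.edge_tension)
    n_up = int(np.floor(C_max / step + 1e-9))  # C never exceeds C_max

    last = None
    for i in range(n_up + 1):
        C = i * step
        result = solve_equilibrium(params, C, guess, cfg)
        if isinstance(result, NonConvergence):
            break
        records.append(ContinuationRecord("ascending", C, result, i))
        last = result
        guess = _interp_state(result, mesh)

    if last is not None and len(records) > 1:
        k_last = records[-1].step_index
        guess = _interp_state(last, mesh)
        for j, k in enumerate(range(k_last - 1, -1, -1)):
            C = k * step
            result = solve_equilibrium(params, C, guess, cfg)
            if isinstance(result, NonConvergence):
                break
            records.append(ContinuationRecord("descending", C, result, j))
            guess = _interp_state(result, mesh)

    return records
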