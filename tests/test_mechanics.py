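"""Membrane mechanics: profiles, energy, ODE system, equilibrium solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from membud import (
    MechanicalParameters,
    MembraneState,
    NonConvergence,
    SolverConfig,
    bending_energy,
    build_mesh,
    flat_state,
    helfrich_energy_density,
    make_profiles,
    ode_rhs,
    solve_equilibrium,
)
from membud.mechanics import PoleSingularityError, SpatialField, MembraneProfiles
from membud.parameters import InvalidParameterError

from helpers import clamped_disc_deflection, normal_balance_residual


# ----------------------------------------------------------------------
# parameters and profiles
# ----------------------------------------------------------------------

def test_patch_and_domain_areas():
    p = MechanicalParameters(patch_radius=25.0, edge_tension=0.01)
    assert p.patch_area == pytest.approx(4 * np.pi * 625, rel=1e-12)
    assert p.total_area == pytest.approx(4 * np.pi * 75**2, rel=1e-12)
    assert p.total_area == pytest.approx(9 * p.patch_area, rel=1e-12)


@pytest.mark.parametrize("bad", [
    dict(patch_radius=-5.0, edge_tension=0.01),
    dict(patch_radius=25.0, edge_tension=0.01, base_rigidity=0.0),
    dict(patch_radius=25.0, edge_tension=-0.01),
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(InvalidParameterError):
        MechanicalParameters(**bad)


def test_profiles_plateaus_and_center():
    p = MechanicalParameters(patch_radius=25.0, edge_tension=0.01,
                             rigidity_multiplier=0.125, patch_pressure=2e-4,
                             patch_curvature=0.01)
    prof = make_profiles(p)
    assert prof.kappa.transition_center == pytest.approx(p.patch_area)
    # patch rigidity 0.125 * 320 = 40, base 320
    assert prof.kappa(0.0) == pytest.approx(40.0, rel=1e-6)
    assert prof.kappa(p.total_area) == pytest.approx(320.0, rel=1e-6)
    assert prof.curvature(0.0) == pytest.approx(0.01, rel=1e-6)
    assert prof.curvature(p.total_area) == pytest.approx(0.0, abs=1e-8)
    assert prof.pressure(0.0) == pytest.approx(2e-4, rel=1e-6)


def test_homogeneous_membrane_gives_uniform_fields():
    p = MechanicalParameters(patch_radius=100.0, edge_tension=0.01)
    prof = make_profiles(p, C_value=0.0)
    a = np.linspace(0, p.total_area, 7)
    assert prof.kappa.is_uniform
    assert np.allclose(prof.curvature(a), 0.0)
    assert np.allclose(prof.pressure(a), 0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(vi=st.floats(-5, 5), vo=st.floats(-5, 5),
       frac=st.floats(0.0, 1.0))
def test_spatial_field_plateau_and_monotone(vi, vo, frac):
    """The profile hits its plateaus at the domain ends and is monotone."""
    center, width = 100.0, 5.0
    f = SpatialField(vi, vo, center, width)
    total = 900.0
    tol = 1e-6 * (abs(vi - vo) + 1e-300)
    assert abs(f(0.0) - vi) <= max(tol, 1e-12)
    assert abs(f(total) - vo) <= max(tol, 1e-12)
    a = np.linspace(0.0, total, 201)
    diffs = np.diff(f(a))
    if vi < vo:
        assert np.all(diffs >= -1e-12)
    else:
        assert np.all(diffs <= 1e-12)
    # derivative consistent with finite differences at an interior point
    x = frac * total
    h = 1e-3
    fd = (f(x + h) - f(x - h)) / (2 * h)
    assert f.derivative(x) == pytest.approx(fd, abs=1e-6 * (abs(vi - vo) + 1))


@pytest.mark.parametrize("H,K,C,kap,kg,expected", [
    (0.02, 0.0, 0.02, 320.0, 50.0, 0.0),
    (0.01, 0.0, 0.0, 320.0, 0.0, 0.032),
    (0.0, 1e-4, 0.0, 320.0, 100.0, 0.01),
])
def test_energy_density_examples(H, K, C, kap, kg, expected):
    assert helfrich_energy_density(H, K, C, kap, kg) == pytest.approx(expected, rel=1e-12)


def test_energy_density_nonnegative_without_gaussian_term():
    rng = np.random.default_rng(0)
    H, C = rng.normal(0, 0.05, 100), rng.normal(0, 0.05, 100)
    W = helfrich_energy_density(H, 0.0, C, 320.0, 0.0)
    assert np.all(W >= 0)


# ----------------------------------------------------------------------
# ODE right-hand side
# ----------------------------------------------------------------------

def test_flat_disc_is_stationary():
    p = MechanicalParameters(patch_radius=100.0, edge_tension=0.04)
    prof = make_profiles(p, C_value=0.0)
    mesh = build_mesh(p.total_area, 200)[1:]
    fs = flat_state(mesh, p.edge_tension)
    d = ode_rhs(mesh, fs.as_matrix(), prof)
    # z, psi, H, L, lambda all stationary; r' = 1/(2 pi r)
    assert np.allclose(d[1:], 0.0, atol=1e-14)
    assert np.allclose(d[0], 1.0 / (2 * np.pi * fs.r), rtol=1e-12)


def test_flat_disc_under_uniform_pressure_feels_only_normal_load():
    p = MechanicalParameters(patch_radius=100.0, edge_tension=0.04)
    pressure = 2e-4
    prof = MembraneProfiles(
        kappa=SpatialField(320.0, 320.0, p.patch_area, 1.0),
        curvature=SpatialField(0.0, 0.0, p.patch_area, 1.0),
        pressure=SpatialField(pressure, pressure, p.patch_area, 1.0),
    )
    mesh = build_mesh(p.total_area, 100)[1:]
    fs = flat_state(mesh, p.edge_tension)
    d = ode_rhs(mesh, fs.as_matrix(), prof)
    assert np.allclose(d[4], pressure / (2 * np.pi), rtol=1e-12)  # L'
    assert np.allclose(d[1], 0.0)  # z'
    assert np.allclose(d[2], 0.0)  # psi'
    assert np.allclose(d[3], 0.0)  # H'
    assert np.allclose(d[5], 0.0)  # lambda'


def test_ode_rhs_rejects_nonpositive_radius():
    p = MechanicalParameters(patch_radius=100.0, edge_tension=0.04)
    prof = make_profiles(p)
    state = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.04])
    with pytest.raises(PoleSingularityError):
        ode_rhs(10.0, state, prof)


# ----------------------------------------------------------------------
# flat state
# ----------------------------------------------------------------------

def test_flat_state_geometry_and_errors():
    mesh = np.array([np.pi, 4 * np.pi, 9 * np.pi])
    fs = flat_state(mesh, 0.01)
    assert fs.r == pytest.approx([1.0, 2.0, 3.0])
    assert np.all(fs.H == 0) and np.all(fs.psi == 0) and np.all(fs.z == 0)
    with pytest.raises(ValueError):
        flat_state(np.array([]), 0.01)
    with pytest.raises(ValueError):
        flat_state(np.array([0.0, 1.0]), 0.01)


# ----------------------------------------------------------------------
# equilibrium solves
# ----------------------------------------------------------------------

def test_flat_membrane_recovered_exactly(flat_solution):
    params, state = flat_solution
    assert isinstance(state, MembraneState)
    assert np.max(np.abs(state.z)) <= 1e-3 * params.patch_radius
    assert np.max(np.abs(state.psi)) <= 1e-3
    assert np.allclose(state.lam, params.edge_tension, atol=1e-6)


def test_small_deflection_matches_clamped_disc_closed_form():
    """Uniform small pressure: solver vs the modified-Bessel closed form."""
    params = MechanicalParameters(patch_radius=100.0, edge_tension=0.05)
    R = np.sqrt(params.total_area / np.pi)
    pressure = 2.0e-6
    cfg = SolverConfig(mesh_points=400)
    mesh = build_mesh(params.total_area, cfg.mesh_points)[1:]
    prof = MembraneProfiles(
        kappa=SpatialField(320.0, 320.0, params.patch_area, 1.0),
        curvature=SpatialField(0.0, 0.0, params.patch_area, 1.0),
        pressure=SpatialField(pressure, pressure, params.patch_area, 1.0),
    )
    st_ = solve_equilibrium(params, 0.0, flat_state(mesh, params.edge_tension),
                            cfg, profiles=prof)
    assert isinstance(st_, MembraneState)
    assert np.max(np.abs(st_.z)) < 0.02 * R  # stays in the linear regime
    z_lin = clamped_disc_deflection(st_.r, R, 320.0, params.edge_tension, pressure)
    assert np.max(np.abs(st_.z - z_lin)) <= 0.05 * np.max(np.abs(z_lin))


def test_boundary_conditions_hold_on_converged_bud(bud_sweep, bud_params):
    state = bud_sweep[len(bud_sweep) // 2].state
    assert abs(state.psi[0]) < 1e-2 and abs(state.L[0]) < 1e-2
    assert abs(state.z[-1]) < 1e-2 and abs(state.psi[-1]) < 1e-2
    assert state.lam[-1] == pytest.approx(bud_params.edge_tension, rel=1e-3)
    assert np.all(state.r > 0)


def test_geometric_consistency_along_mesh(bud_sweep):
    """dr/ds = cos(psi) and dz/ds = sin(psi) hold along converged shapes."""
    state = bud_sweep[len(bud_sweep) // 2].state
    # dr/ds = 2 pi r dr/da, likewise for z
    drda = np.gradient(state.r, state.mesh)
    dzda = np.gradient(state.z, state.mesh)
    cos_err = np.abs(2 * np.pi * state.r * drda - np.cos(state.psi))[3:-3]
    sin_err = np.abs(2 * np.pi * state.r * dzda - np.sin(state.psi))[3:-3]
    assert np.percentile(cos_err, 95) < 0.05
    assert np.percentile(sin_err, 95) < 0.05


def test_force_balance_residual_shrinks_with_tolerance(bud_params):
    """The independent finite-difference residual tracks solver tolerance."""
    residuals = {}
    for tol in (1e-2, 1e-4):
        cfg = SolverConfig(mesh_points=400, tolerance=tol)
        mesh = build_mesh(bud_params.total_area, cfg.mesh_points)[1:]
        guess = flat_state(mesh, bud_params.edge_tension)
        state = None
        for i in range(15):  # walk a short way up the branch
            res = solve_equilibrium(bud_params, i * 0.0007, guess, cfg)
            assert isinstance(res, MembraneState)
            guess = state = res
        residuals[tol] = normal_balance_residual(state, bud_params)
    assert residuals[1e-2] < 0.1
    assert residuals[1e-4] < residuals[1e-2]
    assert residuals[1e-4] < 1e-3


def test_absurd_curvature_returns_nonconvergence(fast_cfg):
    params = MechanicalParameters(patch_radius=100.0, edge_tension=0.02)
    mesh = build_mesh(params.total_area, fast_cfg.mesh_points)[1:]
    res = solve_equilibrium(params, 10.0, flat_state(mesh, params.edge_tension),
                            fast_cfg)
    assert isinstance(res, NonConvergence)
    assert res.C_value == 10.0
    assert not res  # falsy marker


def test_inward_outward_mirror_symmetry(fast_cfg):
    """Flipping the signs of C and p mirrors the shape at equal energy."""
    base = dict(patch_radius=80.0, edge_tension=0.02)
    cfg = fast_cfg
    states = []
    for sign in (+1.0, -1.0):
        params = MechanicalParameters(**base, patch_pressure=sign * 1e-4)
        mesh = build_mesh(params.total_area, cfg.mesh_points)[1:]
        guess = flat_state(mesh, params.edge_tension)
        state = None
        for i in range(11):
            res = solve_equilibrium(params, sign * i * 0.0007, guess, cfg)
            assert isinstance(res, MembraneState)
            guess = state = res
        states.append((params, state))
    (p_out, s_out), (p_in, s_in) = states
    amp = np.max(np.abs(s_out.z))
    assert amp > 0.5  # the bud actually deformed
    assert np.max(np.abs(s_out.z + s_in.z)) < 0.05 * amp
    e_out = bending_energy(s_out, make_profiles(p_out, s_out.C_value))
    e_in = bending_energy(s_in, make_profiles(p_in, s_in.C_value))
    assert e_in == pytest.approx(e_out, rel=1e-2)


def test_solver_config_validation():
    with pytest.raises(InvalidParameterError):
        SolverConfig(tolerance=-1.0)
    with pytest.raises(InvalidParameterError):
        SolverConfig(mesh_points=5)
    assert SolverConfig(mesh_points=2000, max_node_multiplier=1000).max_nodes == 2_000_000
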