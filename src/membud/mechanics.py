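"""Axisymmetric Helfrich membrane equilibrium: energy, ODE system, solver.

Model
-----
The membrane is a thin fluid elastic sheet whose bending energy per unit
area is the Helfrich density

    W = kappa(a) [H - C(a)]^2 + kappa_G K,

with mean curvature H, Gaussian curvature K, spontaneous curvature C and
bending rigidity kappa. Areal incompressibility is enforced by a Lagrange
multiplier field lambda interpreted as membrane tension. Mechanical
equilibrium of an axisymmetric shape reduces to six first-order ODEs in
the cumulative-area coordinate a (dA = da; ds = da / (2 pi r)) for the
state (r, z, psi, H, L, lambda), where psi is the tangent angle to the
base plane and L = r d[kappa (H - C)]/ds is the bending-moment flux:

    r'   = cos(psi) / (2 pi r)
    z'   = sin(psi) / (2 pi r)
    psi' = (2 H - sin(psi)/r) / (2 pi r)
    H'   = L / (2 pi r^2 kappa) - (kappa'/kappa)(H - C) + C'
    L'   = [p + 2 lambda H - 2 kappa (H - C)(2 H^2 - K)
            + 2 kappa H (H - C)^2] / (2 pi)
    lam' = -kappa' (H - C)^2 + 2 kappa (H - C) C'

with K = (sin(psi)/r)(2H - sin(psi)/r). Primes are d/da; kappa', C' are
the area-derivatives of the imposed spatial profiles. The tension
equation is the tangential force balance lambda_{,a} = -dW/da|_explicit
of the variational derivation. Gaussian rigidity is taken uniform, so by
Gauss-Bonnet it drops out of the equilibrium equations entirely and only
shifts the reported energy by a constant.

Boundary conditions (clamped disc): at the inner end psi = 0, L = 0 and
r matches the flat-disc regularity r = sqrt(a0/pi); at the outer edge
z = 0, psi = 0 and lambda = lambda0.

Because flipping the signs of z, C and p maps a solution onto its mirror
image with the same energy, inward and outward budding are energetically
identical; by convention z >= 0 is the budding direction and positive
pressure pushes toward +z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_bvp
from scipy.special import expit

from membud.parameters import MechanicalParameters, InvalidParameterError

__all__ = [
    "SpatialField",
    "MembraneProfiles",
    "MembraneState",
    "NonConvergence",
    "SolverConfig",
    "PoleSingularityError",
    "make_profiles",
    "helfrich_energy_density",
    "ode_rhs",
    "flat_state",
    "solve_equilibrium",
    "bending_energy",
]

_TWO_PI = 2.0 * np.pi
# floor applied to r inside the solver RHS; Newton iterates can wander
# through r <= 0 even when the converged solution is strictly positive
_R_FLOOR = 1.0e-9


class PoleSingularityError(ValueError):
    """The ODE right-hand side was evaluated at r <= 0."""


@dataclass(frozen=True)
class SpatialField:
    """A scalar membrane property as a smooth plateau/transition profile.

    The field takes ``value_inside`` over the central patch and
    ``value_outside`` over the rest of the membrane, joined by a logistic
    sigmoid in the cumulative-area coordinate centred at
    ``transition_center`` with characteristic width ``transition_width``.
    """

    value_inside: float
    value_outside: float
    transition_center: float
    transition_width: float

    def __post_init__(self) -> None:
        if self.transition_width <= 0:
            raise InvalidParameterError("transition_width must be positive")

    def __call__(self, a):
        s = expit((np.asarray(a, dtype=float) - self.transition_center)
                  / self.transition_width)
        return self.value_inside + (self.value_outside - self.value_inside) * s

    def derivative(self, a):
        """d(field)/da."""
        s = expit((np.asarray(a, dtype=float) - self.transition_center)
                  / self.transition_width)
        return (self.value_outside - self.value_inside) * s * (1.0 - s) \
            / self.transition_width

    @property
    def is_uniform(self) -> bool:
        return self.value_inside == self.value_outside


@dataclass(frozen=True)
class MembraneProfiles:
    """The three spatially varying mechanical profiles of one simulation."""

    kappa: SpatialField
    curvature: SpatialField
    pressure: SpatialField


def make_profiles(
    params: MechanicalParameters,
    C_value: Optional[float] = None,
    transition_width_frac: float = 0.05,
) -> MembraneProfiles:
    """Build the rigidity, spontaneous-curvature and pressure profiles.

    Inside the patch (area < 4 pi r^2) the rigidity is
    ``rigidity_multiplier * base_rigidity``, the spontaneous curvature is
    ``C_value`` (defaulting to ``params.patch_curvature``) and the normal
    pressure is ``params.patch_pressure``; outside, rigidity relaxes to the
    base value and curvature and pressure to zero. All three transitions
    are centred at the patch area with width
    ``transition_width_frac * patch_area``.
    """
    if C_value is None:
        C_value = params.patch_curvature
    center = params.patch_area
    width = transition_width_frac * params.patch_area
    return MembraneProfiles(
        kappa=SpatialField(params.patch_rigidity, params.base_rigidity,
                           center, width),
        curvature=SpatialField(float(C_value), 0.0, center, width),
        pressure=SpatialField(params.patch_pressure, 0.0, center, width),
    )


def helfrich_energy_density(H, K, C, kappa, kappa_g=0.0):
    """Helfrich bending energy per unit area: kappa (H-C)^2 + kappa_G K."""
    H = np.asarray(H, dtype=float)
    return kappa * (H - C) ** 2 + kappa_g * K


@dataclass
class MembraneState:
    """A membrane configuration on a cumulative-area mesh.

    ``mesh`` holds the area coordinate a in (0, A_total]; the six state
    arrays give the radial distance r (nm), height z (nm), tangent angle
    psi (rad), mean curvature H (1/nm), bending-moment flux L (pN) and
    tension lambda (pN/nm) at each mesh point. ``converged`` records
    whether this state came out of a successful equilibrium solve;
    ``C_value`` is the patch spontaneous curvature it was solved at and
    ``warm_start_C`` the curvature of the state used as its initial guess
    (None for a cold start).
    """

    mesh: np.ndarray
    r: np.ndarray
    z: np.ndarray
    psi: np.ndarray
    H: np.ndarray
    L: np.ndarray
    lam: np.ndarray
    converged: bool = False
    params: Optional[MechanicalParameters] = None
    C_value: float = 0.0
    warm_start_C: Optional[float] = None

    def as_matrix(self) -> np.ndarray:
        """State as the (6, n) array consumed by the BVP solver."""
        return np.vstack([self.r, self.z, self.psi, self.H, self.L, self.lam])

    @property
    def max_psi(self) -> float:
        return float(np.max(self.psi))

    def curve(self) -> np.ndarray:
        """The (n, 2) profile curve (r, z) in nm."""
        return np.column_stack([self.r, self.z])

    def gaussian_curvature(self) -> np.ndarray:
        sin_over_r = np.sin(self.psi) / self.r
        return sin_over_r * (2.0 * self.H - sin_over_r)


@dataclass(frozen=True)
class NonConvergence:
    """Marker returned when the BVP solver fails to find an equilibrium."""

    C_value: float
    reason: str = "solver did not converge"

    def __bool__(self) -> bool:  # lets callers write `if not result:`
        return False


@dataclass(frozen=True)
class SolverConfig:
    """Settings of the collocation solve.

    tolerance
        Relative residual tolerance passed to the collocation solver.
    mesh_points
        Number of points of the squared base mesh.
    max_node_multiplier
        The solver may refine up to mesh_points * max_node_multiplier nodes.
    transition_width_frac
        Width of the patch/base sigmoid transition as a fraction of the
        patch area.
    """

    tolerance: float = 1.0e-2
    mesh_points: int = 2000
    max_node_multiplier: int = 1000
    transition_width_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise InvalidParameterError("tolerance must be positive")
        if self.mesh_points < 10:
            raise InvalidParameterError("mesh_points must be >= 10")
        if self.max_node_multiplier < 1:
            raise InvalidParameterError("max_node_multiplier must be >= 1")
        if self.transition_width_frac <= 0:
            raise InvalidParameterError("transition_width_frac must be positive")

    @property
    def max_nodes(self) -> int:
        return self.mesh_points * self.max_node_multiplier


def _rhs(a, y, profiles: MembraneProfiles, r_floor: float = _R_FLOOR):
    """Vectorized right-hand side of the six-ODE system (see module docs)."""
    r, z, psi, H, L, lam = y
    r = np.maximum(r, r_floor)
    kappa = profiles.kappa(a)
    dkappa = profiles.kappa.derivative(a)
    C = profiles.curvature(a)
    dC = profiles.curvature.derivative(a)
    p = profiles.pressure(a)

    two_pi_r = _TWO_PI * r
    sin_psi = np.sin(psi)
    sin_over_r = sin_psi / r
    psi_s = 2.0 * H - sin_over_r          # d psi / ds
    K = sin_over_r * psi_s                # Gaussian curvature
    HmC = H - C

    dr = np.cos(psi) / two_pi_r
    dz = sin_psi / two_pi_r
    dpsi = psi_s / two_pi_r
    dH = L / (two_pi_r * r * kappa) - (dkappa / kappa) * HmC + dC
    dL = (p + 2.0 * lam * H
          - 2.0 * kappa * HmC * (2.0 * H * H - K)
          + 2.0 * kappa * H * HmC * HmC) / _TWO_PI
    dlam = -dkappa * HmC * HmC + 2.0 * kappa * HmC * dC
    return np.vstack([dr, dz, dpsi, dH, dL, dlam])


def ode_rhs(a, state, profiles: MembraneProfiles):
    """d/da of the six-vector (r, z, psi, H, L, lambda) at area coordinate a.

    Raises :class:`PoleSingularityError` if any radial coordinate is
    non-positive; the solver regularizes the pole by imposing the inner
    boundary at the first mesh node instead of a = 0.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(state, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if np.any(y[0] <= 0):
        raise PoleSingularityError("ode_rhs evaluated at r <= 0")
    out = _rhs(a, y, profiles, r_floor=0.0)
    return out[:, 0] if squeeze else out


def flat_state(mesh, lam0: float) -> MembraneState:
    """The flat-disc configuration: z = psi = H = L = 0, lambda = lam0.

    The radial coordinate is r(a) = sqrt(a / pi), the flat disc enclosing
    area a. This is an exact equilibrium for C = 0, p = 0 and serves as
    the cold-start initial guess of every continuation sweep.
    """
    mesh = np.asarray(mesh, dtype=float)
    if mesh.size == 0:
        raise ValueError("mesh must be non-empty")
    if mesh[0] <= 0 or np.any(np.diff(mesh) <= 0):
        raise ValueError("mesh must be strictly increasing with first point > 0")
    zeros = np.zeros_like(mesh)
    return MembraneState(
        mesh=mesh,
        r=np.sqrt(mesh / np.pi),
        z=zeros.copy(),
        psi=zeros.copy(),
        H=zeros.copy(),
        L=zeros.copy(),
        lam=np.full_like(mesh, float(lam0)),
        converged=True,
        C_value=0.0,
    )


def solve_equilibrium(
    params: MechanicalParameters,
    C_value: float,
    initial_guess: MembraneState,
    solver_cfg: Optional[SolverConfig] = None,
    profiles: Optional[MembraneProfiles] = None,
):
    """Solve the equilibrium BVP at patch curvature ``C_value``.

    The solve runs on the mesh carried by ``initial_guess`` (the converged
    solution is re-evaluated on that same mesh, keeping chained warm starts
    on the canonical grid). Returns a converged :class:`MembraneState`, or
    a :class:`NonConvergence` marker if the collocation solver fails —
    solver failure is an expected outcome of the continuation protocol,
    never an exception.

    ``profiles`` overrides the default patch profiles, e.g. to impose a
    spatially uniform load.
    """
    cfg = solver_cfg or SolverConfig()
    if profiles is None:
        profiles = make_profiles(
            params, C_value, transition_width_frac=cfg.transition_width_frac
        )
    a = np.asarray(initial_guess.mesh, dtype=float)
    y0 = initial_guess.as_matrix()
    a0 = a[0]
    r0 = np.sqrt(a0 / np.pi)
    lam0 = params.edge_tension

    def fun(x, y):
        return _rhs(x, y, profiles)

    def bc(ya, yb):
        # inner: psi = 0, L = 0, r regular; outer: z = 0, psi = 0, lam = lam0
        return np.array([
            ya[2], ya[4], ya[0] - r0,
            yb[1], yb[2], yb[5] - lam0,
        ])

    with np.errstate(all="ignore"):
        try:
            sol = solve_bvp(fun, bc, a, y0, tol=cfg.tolerance,
                            max_nodes=cfg.max_nodes)
        except Exception as exc:  # singular Jacobian, overflow, ...
            return NonConvergence(C_value, f"solver raised: {exc}")
    if sol.status != 0:
        return NonConvergence(C_value, sol.message)
    Y = sol.sol(a)
    if not np.all(np.isfinite(Y)) or np.any(Y[0] <= 0):
        return NonConvergence(C_value, "non-finite or non-positive-radius solution")
    return MembraneState(
        mesh=a, r=Y[0], z=Y[1], psi=Y[2], H=Y[3], L=Y[4], lam=Y[5],
        converged=True, params=params, C_value=float(C_value),
        warm_start_C=initial_guess.C_value if initial_guess.converged else None,
    )


def bending_energy(state: MembraneState, profiles: MembraneProfiles,
                   kappa_g: float = 0.0) -> float:
    """Total Helfrich bending energy of a state, pN nm.

    In the area parametrization dA = da, so the energy is the trapezoidal
    integral of the energy density along the mesh. A uniform kappa_G adds
    the Gauss-Bonnet term, constant across shapes with the same boundary.
    """
    W = helfrich_energy_density(
        state.H, state.gaussian_curvature(), profiles.curvature(state.mesh),
        profiles.kappa(state.mesh), kappa_g,
    )
    return float(np.trapezoid(W, state.mesh))
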