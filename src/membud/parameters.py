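"""Mechanical parameter set and the two sampled parameter spaces.

All quantities are dimensional: lengths in nm, forces in pN, so tension is
pN/nm, pressure pN/nm^2, bending rigidity pN nm and curvature 1/nm.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MechanicalParameters",
    "PRESSURE_SPACE",
    "RIGIDITY_SPACE",
    "SPACES",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """A mechanical parameter is outside its physically meaningful domain."""


@dataclass(frozen=True)
class MechanicalParameters:
    """One point in mechanical parameter space driving a simulation.

    Parameters
    ----------
    patch_radius : float
        Radius of the nascent bud, nm. The mechanically altered patch has
        area ``4 pi r^2`` (the full area of a sphere of that radius, so the
        patch holds enough membrane to wrap a bud of radius ``r``); the
        simulation domain is nine times larger, ``4 pi (3 r)^2``.
    edge_tension : float
        Membrane tension imposed at the clamped outer edge, pN/nm.
    base_rigidity : float
        Bending rigidity of the membrane outside the patch, pN nm.
    rigidity_multiplier : float
        Dimensionless multiplier: patch rigidity = multiplier * base_rigidity.
    patch_pressure : float
        Outward normal pressure applied over the patch, pN/nm^2.
    patch_curvature : float
        Spontaneous curvature of the patch, 1/nm. During a continuation
        sweep this field is varied step by step; the value stored here is
        used when a single solve is requested directly.
    gaussian_rigidity : float
        Gaussian (saddle-splay) rigidity, pN nm. Taken spatially uniform,
        so it contributes a topological constant to the energy and drops
        out of the equilibrium equations.
    """

    patch_radius: float
    edge_tension: float
    base_rigidity: float = 320.0
    rigidity_multiplier: float = 1.0
    patch_pressure: float = 0.0
    patch_curvature: float = 0.0
    gaussian_rigidity: float = 0.0

    def __post_init__(self) -> None:
        if not self.patch_radius > 0:
            raise InvalidParameterError(
                f"patch_radius must be positive, got {self.patch_radius}"
            )
        if not self.base_rigidity > 0:
            raise InvalidParameterError(
                f"base_rigidity must be positive, got {self.base_rigidity}"
            )
        if not self.rigidity_multiplier > 0:
            raise InvalidParameterError(
                f"rigidity_multiplier must be positive, got {self.rigidity_multiplier}"
            )
        if not self.edge_tension > 0:
            raise InvalidParameterError(
                f"edge_tension must be positive, got {self.edge_tension}"
            )

    @property
    def patch_area(self) -> float:
        """Area of the mechanically altered patch, nm^2 (= 4 pi r^2)."""
        return 4.0 * np.pi * self.patch_radius**2

    @property
    def total_area(self) -> float:
        """Area of the whole simulation domain, nm^2 (= 9 * patch area)."""
        return 4.0 * np.pi * (3.0 * self.patch_radius) ** 2

    @property
    def patch_rigidity(self) -> float:
        """Bending rigidity inside the patch, pN nm."""
        return self.rigidity_multiplier * self.base_rigidity

    def to_dict(self) -> dict:
        return asdict(self)


# The two 4-D spaces sampled for dataset generation. Each entry maps a
# feature name to its closed sampling range; `fixed` pins the parameter the
# space does not vary. Curvature is not drawn at random: it is swept by
# continuation in fixed steps, so its range here is used only for feature
# normalization and phase-map axes.
PRESSURE_SPACE = {
    "name": "pressure",
    "features": ("curvature", "tension", "patch_radius", "pressure"),
    "ranges": {
        "curvature": (0.0, 0.07),
        "tension": (0.003, 0.15),
        "patch_radius": (25.0, 500.0),
        "pressure": (0.0, 3.0e-4),
    },
    "fixed": {"rigidity_multiplier": 1.0},
}

RIGIDITY_SPACE = {
    "name": "rigidity",
    "features": ("curvature", "tension", "patch_radius", "rigidity_multiplier"),
    "ranges": {
        "curvature": (0.0, 0.07),
        "tension": (0.003, 0.15),
        "patch_radius": (25.0, 500.0),
        "rigidity_multiplier": (0.125, 1.25),
    },
    "fixed": {"patch_pressure": 0.0},
}

SPACES = {"pressure": PRESSURE_SPACE, "rigidity": RIGIDITY_SPACE}
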