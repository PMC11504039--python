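"""Analytic velocity fields on structured grids, with known Q-criterion.

Four canonical planar fields (uniform along z):

- ``rotation``: solid-body rotation at rate ω, u = ω(−y, x, 0); Q = ω².
- ``shear``: simple shear u = (γ·y, 0, 0); rotation and strain balance, Q = 0.
- ``strain``: pure planar strain u = (α·x, −α·y, 0); Q = −α².
- ``lamb_oseen``: a Lamb–Oseen vortex, u_θ = Γ/(2πr)(1 − exp(−r²/r_c²));
  Q(r) = (u_θ/r)·du_θ/dr, positive in the core and negative outside.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError
from ..wallshear import VelocityGrid

__all__ = ["gen_velocity_grid"]

KINDS = ("rotation", "shear", "strain", "lamb_oseen")


def gen_velocity_grid(
    kind: str,
    magnitude: float = 10.0,
    grid_shape: tuple = (16, 16, 4),
    spacing: float = 1e-3,
    core_radius: float = 3e-3,
) -> tuple[VelocityGrid, dict]:
    """Sample an analytic velocity field; returns ``(grid, truth)``.

    ``magnitude`` is ω, γ or α in 1/s (circulation Γ in m²/s for lamb_oseen);
    ``truth["q_field"]`` holds the analytic Q on the same grid.
    """
    if kind not in KINDS:
        raise ParameterError(f"unknown velocity field kind: {kind!r} (choose from {KINDS})")
    if any(s < 4 for s in grid_shape):
        raise ParameterError("grid_shape must be >= 4 per axis")
    if spacing <= 0:
        raise ParameterError("spacing must be positive")

    nx, ny, nz = grid_shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    z = (np.arange(nz) - (nz - 1) / 2.0) * spacing
    X, Y, _Z = np.meshgrid(x, y, z, indexing="ij")

    u = np.zeros(grid_shape + (3,))
    if kind == "rotation":
        u[..., 0] = -magnitude * Y
        u[..., 1] = magnitude * X
        q_true = np.full(grid_shape, magnitude**2)
    elif kind == "shear":
        u[..., 0] = magnitude * Y
        q_true = np.zeros(grid_shape)
    elif kind == "strain":
        u[..., 0] = magnitude * X
        u[..., 1] = -magnitude * Y
        q_true = np.full(grid_shape, -(magnitude**2))
    else:  # lamb_oseen
        r = np.hypot(X, Y)
        r_safe = np.where(r > 0, r, 1.0)
        utheta = magnitude / (2.0 * np.pi * r_safe) * (1.0 - np.exp(-(r**2) / core_radius**2))
        utheta = np.where(r > 0, utheta, 0.0)
        u[..., 0] = -utheta * Y / r_safe
        u[..., 1] = utheta * X / r_safe
        # d(u_θ)/dr, analytic
        g = 1.0 - np.exp(-(r**2) / core_radius**2)
        dudr = magnitude / (2.0 * np.pi) * (
            -g / r_safe**2 + (2.0 * r_safe / core_radius**2) * np.exp(-(r**2) / core_radius**2) / r_safe
        )
        q_true = np.where(r > 0, utheta / r_safe * dudr, (magnitude / (np.pi * core_radius**2)) ** 2)

    grid = VelocityGrid(spacing=(spacing, spacing, spacing), velocity=u)
    return grid, {"q_field": q_true, "kind": kind, "magnitude": magnitude}
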