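"""Leaflet hemodynamic field analytics: WSS, TAWSS, OSI and the Q-criterion.

The wall shear stress (WSS) vector τ_w = μ ∂u/∂n̂ is the tangential fluid
traction on a surface. Over one cardiac cycle of period T the time-averaged
wall shear stress and the oscillatory shear index are

    TAWSS = (1/T) ∫₀ᵀ ‖τ_w‖ dt
    OSI   = ½ (1 − ‖∫₀ᵀ τ_w dt‖ / (T · TAWSS))

OSI ranges from 0 (unidirectional shear) to 0.5 (purely oscillatory, zero-mean
shear); it is defined as 0 where TAWSS vanishes. Vortical structures in a
velocity field are identified by the Q-criterion,

    Q = ½ (‖Ω‖²_F − ‖S‖²_F),

with S and Ω the symmetric and antisymmetric parts of the velocity gradient;
Q > 0 where rotation dominates strain.

Stresses are carried in dynes/cm² internally (1 Pa = 10 dynes/cm²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError

__all__ = [
    "WSSSurfaceField",
    "VelocityGrid",
    "HemodynamicFieldSummary",
    "wss_from_near_wall_profile",
    "compute_tawss",
    "compute_osi",
    "area_weighted_mean",
    "summarize_field",
    "compute_q_criterion",
]

PA_TO_DYNES_CM2 = 10.0


@dataclass
class WSSSurfaceField:
    """Triangulated leaflet surface with a per-node WSS vector time series.

    nodes: (N, 3) coordinates in mm; triangles: (M, 3) node indices;
    times: (K,) s spanning exactly one cycle (last sample at t₀ + T, identified
    with the first); wss_vectors: (K, N, 3) in dynes/cm².
    """

    nodes: np.ndarray
    triangles: np.ndarray
    times: np.ndarray
    wss_vectors: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.wss_vectors = np.asarray(self.wss_vectors, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise DataError("nodes must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise DataError("triangles must be (M, 3)")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= len(self.nodes):
            raise DataError("triangle indices out of range")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        K, N = self.times.size, self.nodes.shape[0]
        if self.wss_vectors.shape != (K, N, 3):
            raise DataError(f"wss_vectors must be (K={K}, N={N}, 3)")
        if not np.all(np.isfinite(self.wss_vectors)):
            raise DataError("wss_vectors contain non-finite values")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class HemodynamicFieldSummary:
    tawss_per_node: np.ndarray  # dynes/cm²
    osi_per_node: np.ndarray
    tawss_mean: float
    osi_mean: float


@dataclass
class VelocityGrid:
    """Velocity vectors on a uniform structured grid.

    spacing: (dx, dy, dz) in m; velocity: (nx, ny, nz, 3) in m/s.
    """

    spacing: tuple
    velocity: np.ndarray

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DataError("spacing must be three positive lengths")
        if self.velocity.ndim != 4 or self.velocity.shape[-1] != 3:
            raise DataError("velocity must be (nx, ny, nz, 3)")


def wss_from_near_wall_profile(offsets, tangential_velocity, mu: float = 1.07) -> float:
    """Instantaneous WSS (dynes/cm²) from a near-wall tangential velocity profile.

    ``offsets`` are wall-normal distances in m (first must be the wall itself,
    at zero velocity); ``tangential_velocity`` in m/s; ``mu`` in cP. A one-sided
    first-order finite difference at the wall gives ∂u/∂n̂.
    """
    n = np.asarray(offsets, dtype=float)
    u = np.asarray(tangential_velocity, dtype=float)
    if n.size < 2 or n.size != u.size:
        raise DataError("need matched offset/velocity samples (>= 2)")
    if n[0] != 0.0:
        raise DomainError("first offset must be the wall (0 m)")
    if np.any(n[1:] <= 0) or np.any(np.diff(n) <= 0):
        raise DomainError("offsets must be positive and increasing beyond the wall")
    if u[0] != 0.0:
        raise DataError("no-slip wall sample must have zero velocity")
    dudn = (u[1] - u[0]) / (n[1] - n[0])  # 1/s
    tau_pa = mu * 1e-3 * dudn
    return float(tau_pa * PA_TO_DYNES_CM2)


def compute_tawss(field: WSSSurfaceField) -> np.ndarray:
    """Per-node TAWSS (dynes/cm²) by trapezoidal quadrature over the cycle."""
    mag = np.linalg.norm(field.wss_vectors, axis=2)  # (K, N)
    return np.trapezoid(mag, field.times, axis=0) / field.period


def compute_osi(field: WSSSurfaceField) -> np.ndarray:
    """Per-node oscillatory shear index in [0, 0.5].

    Nodes with zero TAWSS (no shear at all) are assigned OSI = 0: absent flow
    has no oscillatory character.
    """
    T = field.period
    tawss = compute_tawss(field)
    integral = np.trapezoid(field.wss_vectors, field.times, axis=0)  # (N, 3)
    num = np.linalg.norm(integral, axis=1)
    osi = np.zeros_like(tawss)
    nz = tawss > 0
    osi[nz] = 0.5 * (1.0 - num[nz] / (T * tawss[nz]))
    return osi


def _triangle_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = nodes[triangles[:, 0]]
    b = nodes[triangles[:, 1]]
    c = nodes[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def area_weighted_mean(values, nodes, triangles) -> float:
    """Surface mean of a per-node scalar, weighted by one-third incident area."""
    values = np.asarray(values, dtype=float)
    nodes = np.asarray(nodes, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    areas = _triangle_areas(nodes, triangles)
    w = np.zeros(len(nodes))
    for k in range(3):
        np.add.at(w, triangles[:, k], areas / 3.0)
    total = w.sum()
    if total <= 0:
        raise DataError("degenerate surface: total area is zero")
    return float(np.dot(w, values) / total)


def summarize_field(field: WSSSurfaceField) -> HemodynamicFieldSummary:
    """TAWSS and OSI per node plus their area-weighted surface means."""
    tawss = compute_tawss(field)
    osi = compute_osi(field)
    return HemodynamicFieldSummary(
        tawss_per_node=tawss,
        osi_per_node=osi,
        tawss_mean=area_weighted_mean(tawss, field.nodes, field.triangles),
        osi_mean=area_weighted_mean(osi, field.nodes, field.triangles),
    )


def compute_q_criterion(grid: VelocityGrid) -> np.ndarray:
    """Q-criterion (1/s²) per cell from central-difference velocity gradients."""
    u = grid.velocity
    if any(s < 4 for s in u.shape[:3]):
        raise DataError("grid must be at least 4 cells per axis for central differences")
    dx, dy, dz = grid.spacing
    # J[..., i, j] = ∂u_i/∂x_j
    J = np.empty(u.shape[:3] + (3, 3))
    for i in range(3):
        gx, gy, gz = np.gradient(u[..., i], dx, dy, dz)
        J[..., i, 0], J[..., i, 1], J[..., i, 2] = gx, gy, gz
    Jt = np.swapaxes(J, -1, -2)
    S = 0.5 * (J + Jt)
    W = 0.5 * (J - Jt)
    normsq = lambda A: np.sum(A**2, axis=(-2, -1))
    return 0.5 * (normsq(W) - normsq(S))
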