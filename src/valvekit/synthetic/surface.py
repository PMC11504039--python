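"""Synthetic leaflet WSS surface fields with closed-form TAWSS/OSI truth.

The leaflet stand-in is a triangulated unit disk (scaled to a physical
radius); the radial coordinate r ∈ [0, 1] stands in for belly → free-edge
position, and the shear amplitude ramps linearly with r from
``belly_amplitude`` to ``edge_amplitude`` (real leaflets see low shear in the
belly and higher shear near the free edge). The temporal basis is a square
wave with forward duty f: shear points along +x for the first f·T of the
cycle and along −x for the rest, so the continuous-time ground truths are

    TAWSS(r) = A(r),            OSI = ½ (1 − |2f − 1|)

at every node (OSI = 0.5 exactly for the symmetric f = 0.5 wave).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from ..errors import ParameterError
from ..wallshear import WSSSurfaceField

__all__ = ["WSSFieldParams", "gen_wss_surface_field", "bioreactor_preset"]


@dataclass
class WSSFieldParams:
    n_nodes: int = 400
    cycle_period: float = 0.857  # s
    n_timesteps: int = 200
    belly_amplitude: float = 5.0  # dynes/cm²
    edge_amplitude: float = 20.0  # dynes/cm²
    forward_duty: float = 0.5
    noise_sd: float = 0.0  # dynes/cm²
    seed: int = 0
    leaflet_radius_mm: float = 12.0

    def validate(self) -> None:
        if self.n_nodes < 8:
            raise ParameterError("n_nodes must be >= 8")
        if self.cycle_period <= 0:
            raise ParameterError("cycle_period must be positive")
        if self.n_timesteps < 8:
            raise ParameterError("n_timesteps must be >= 8")
        if self.belly_amplitude < 0 or self.edge_amplitude < 0:
            raise ParameterError("belly_amplitude/edge_amplitude must be >= 0")
        if not 0.0 < self.forward_duty <= 1.0:
            raise ParameterError("forward_duty must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def bioreactor_preset(**overrides) -> WSSFieldParams:
    """Oscillatory-flow conditioning preset: duty 0.5, 3.5 dynes/cm² everywhere."""
    base = dict(belly_amplitude=3.5, edge_amplitude=3.5, forward_duty=0.5)
    base.update(overrides)
    return WSSFieldParams(**base)


def _disk_mesh(n_nodes: int, radius: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sunflower-packed disk points + Delaunay triangulation; returns r in [0,1]."""
    i = np.arange(n_nodes)
    r = np.sqrt((i + 0.5) / n_nodes)
    theta = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    tri = Delaunay(xy)
    nodes = np.column_stack([radius * xy, np.zeros(n_nodes)])
    return nodes, tri.simplices.copy(), r


def gen_wss_surface_field(params: WSSFieldParams) -> tuple[WSSSurfaceField, dict]:
    """Generate a WSS surface field plus its analytic per-node ground truth."""
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)

    nodes, triangles, r = _disk_mesh(p.n_nodes, p.leaflet_radius_mm)
    amplitude = p.belly_amplitude + (p.edge_amplitude - p.belly_amplitude) * r

    K = p.n_timesteps
    times = np.linspace(0.0, p.cycle_period, K + 1)
    # square wave from integer sample indices (robust to float phase rounding);
    # last sample wraps to the first
    k = np.arange(K + 1) % K
    w = np.where(k + 1e-9 < p.forward_duty * K, 1.0, -1.0)

    wss = np.zeros((K + 1, p.n_nodes, 3))
    wss[:, :, 0] = w[:, None] * amplitude[None, :]
    if p.noise_sd > 0:
        wss = wss + rng.normal(0.0, p.noise_sd, wss.shape)
        wss[-1] = wss[0]  # keep the periodic identification exact

    field = WSSSurfaceField(nodes=nodes, triangles=triangles, times=times, wss_vectors=wss)
    truth = {
        "tawss_per_node": amplitude,
        "osi_per_node": np.full(p.n_nodes, 0.5 * (1.0 - abs(2.0 * p.forward_duty - 1.0))),
        "radial_coordinate": r,
        "forward_duty": p.forward_duty,
    }
    return field, truth
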