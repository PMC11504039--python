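"""Pulse-duplicator hydrodynamic metrics.

Given ventricular pressure, aortic pressure and transaortic flow recorded over
one or more cardiac cycles, this module computes the four standard valve
functionality metrics — regurgitant fraction (RF), mean systolic pressure drop
(ΔP), root-mean-square forward flow (Q_RMS) and effective orifice area (EOA) —
plus the Reynolds number of the test fluid.

Conventions follow bench practice for pulse-duplicator testing (ISO 5840
style): waveforms are ensemble-averaged over 10 cycles, ΔP and Q_RMS are taken
over the forward-flow (positive-flow) window, RF is the retrograde volume
(closing + leakage) as a percentage of the forward volume, and

    EOA [cm²] = Q_RMS / (51.6 · sqrt(ΔP / ρ))

with Q_RMS in mL/s, ΔP in mmHg and ρ in g/cm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DomainError

__all__ = [
    "PressureFlowWaveform",
    "FluidProperties",
    "CycleSegmentation",
    "HydrodynamicMetrics",
    "ensemble_average",
    "detect_forward_flow",
    "compute_delta_p",
    "compute_qrms",
    "compute_rf",
    "compute_eoa",
    "compute_reynolds",
    "analyze_waveform",
]

#: conversion constant in the Gorlin-type EOA formula (mL/s, mmHg, g/cm³ -> cm²)
EOA_CONSTANT = 51.6


@dataclass
class FluidProperties:
    """Test-fluid properties. Defaults are 0.9% saline at 20 °C."""

    density: float = 1007.0  # kg/m³
    dynamic_viscosity: float = 1.07  # cP

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError("density must be positive")
        if self.dynamic_viscosity <= 0:
            raise DomainError("dynamic_viscosity must be positive")

    @property
    def density_g_cm3(self) -> float:
        return self.density / 1000.0

    @property
    def viscosity_pa_s(self) -> float:
        return self.dynamic_viscosity * 1e-3


@dataclass
class PressureFlowWaveform:
    """Sampled pressure/flow channels on a uniform time grid.

    Attributes
    ----------
    time : s, strictly increasing uniform grid
    p_vent, p_ao : mmHg
    q : transaortic flow, mL/s (positive = forward)
    cycle_period : s
    """

    time: np.ndarray
    p_vent: np.ndarray
    p_ao: np.ndarray
    q: np.ndarray
    cycle_period: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.p_vent = np.asarray(self.p_vent, dtype=float)
        self.p_ao = np.asarray(self.p_ao, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        n = self.time.size
        if not (self.p_vent.size == self.p_ao.size == self.q.size == n):
            raise DataError("waveform channels must have equal length")
        if n < 2:
            raise DataError("waveform needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise DataError("time grid must be uniform")
        if self.cycle_period <= 0:
            raise DataError("cycle_period must be positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_period / self.dt))

    @property
    def n_cycles(self) -> int:
        return self.time.size // self.samples_per_cycle


@dataclass
class CycleSegmentation:
    """Index bookkeeping for one averaged cycle."""

    cycle_bounds: list = field(default_factory=list)  # [(i0, i1)] half-open
    forward_flow_windows: list = field(default_factory=list)  # [(i0, i1)]


@dataclass
class HydrodynamicMetrics:
    rf: float  # %
    delta_p: float  # mmHg
    q_rms: float  # mL/s
    eoa: float  # cm²


def _first_upstroke(q: np.ndarray, threshold: float) -> int:
    """Index of the first upward crossing of ``threshold``."""
    above = q > threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if crossings.size == 0:
        return 0
    return int(crossings[0] + 1)


def ensemble_average(w: PressureFlowWaveform, n_cycles: int = 10) -> PressureFlowWaveform:
    """Average a multi-cycle recording into one representative cycle.

    Cycles are phase-aligned on the first forward-flow upstroke and averaged
    sample-by-sample. Raises :class:`DataError` if the recording holds fewer
    than ``n_cycles`` complete cycles.
    """
    spc = w.samples_per_cycle
    if spc < 2:
        raise DataError("cycle_period too short for the sampling rate")
    threshold = 0.02 * float(np.max(np.abs(w.q))) if np.any(w.q != 0) else 0.0
    phase = _first_upstroke(w.q, threshold) % spc
    usable = (w.time.size - phase) // spc
    if usable < n_cycles:
        # retry from the very start: a recording that begins exactly at the
        # upstroke should not lose its first cycle to phase detection
        phase = 0
        usable = w.time.size // spc
    if usable < n_cycles:
        raise DataError(
            f"requested {n_cycles} cycles but recording holds only {usable} "
            f"complete cycles ({w.time.size} samples, {spc} per cycle)"
        )
    stack = lambda x: x[phase : phase + n_cycles * spc].reshape(n_cycles, spc)
    return PressureFlowWaveform(
        time=np.arange(spc) * w.dt,
        p_vent=stack(w.p_vent).mean(axis=0),
        p_ao=stack(w.p_ao).mean(axis=0),
        q=stack(w.q).mean(axis=0),
        cycle_period=w.cycle_period,
    )


def detect_forward_flow(
    w: PressureFlowWaveform,
    threshold_fraction: float = 0.02,
    hysteresis_samples: int = 2,
) -> CycleSegmentation:
    """Locate the forward-flow (ejection) window on a single averaged cycle.

    The window is the contiguous run of samples with q above a small fraction
    of the peak absolute flow; gaps up to ``hysteresis_samples`` long are
    bridged so threshold chatter near the crossings does not split the window.
    """
    q = w.q
    if not np.any(q > 0):
        raise DataError("no positive flow in waveform")
    thr = threshold_fraction * float(np.max(np.abs(q)))
    above = q > thr
    # hysteresis: bridge short sub-threshold gaps
    idx = np.flatnonzero(above)
    gaps = np.diff(idx)
    for k in np.flatnonzero((gaps > 1) & (gaps <= hysteresis_samples + 1)):
        above[idx[k] : idx[k + 1]] = True
    # maximal run, by integrated flow
    padded = np.concatenate(([False], above, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    volumes = [float(np.trapezoid(q[s:e], dx=w.dt)) for s, e in zip(starts, ends)]
    best = int(np.argmax(volumes))
    s, e = int(starts[best]), int(ends[best])
    # hysteresis exit level: entered at thr, extend down to the zero crossing
    while s > 0 and q[s - 1] > 0:
        s -= 1
    while e < q.size and q[e] > 0:
        e += 1
    window = (s, e)
    return CycleSegmentation(
        cycle_bounds=[(0, q.size)], forward_flow_windows=[window]
    )


def _window(seg: CycleSegmentation) -> tuple[int, int]:
    if not seg.forward_flow_windows:
        raise DataError("segmentation holds no forward-flow window")
    i0, i1 = seg.forward_flow_windows[0]
    if i1 <= i0:
        raise DataError("empty forward-flow window")
    return i0, i1


def compute_delta_p(
    w: PressureFlowWaveform, seg: CycleSegmentation, mode: str = "mean"
) -> float:
    """Transvalvular pressure drop (mmHg) over the forward-flow window.

    ``mode="mean"`` (default) averages p_vent − p_ao over the window;
    ``mode="peak"`` returns the window maximum.
    """
    i0, i1 = _window(seg)
    dp = w.p_vent[i0:i1] - w.p_ao[i0:i1]
    if mode == "mean":
        return float(np.mean(dp))
    if mode == "peak":
        return float(np.max(dp))
    raise DomainError(f"unknown delta_p mode: {mode!r}")


def compute_qrms(w: PressureFlowWaveform, seg: CycleSegmentation) -> float:
    """Root-mean-square flow (mL/s) over the forward-flow window."""
    i0, i1 = _window(seg)
    q = w.q[i0:i1]
    msq = np.trapezoid(q**2, dx=w.dt) / ((i1 - i0 - 1) * w.dt)
    return float(np.sqrt(msq))


def compute_rf(w: PressureFlowWaveform, seg: CycleSegmentation) -> float:
    """Regurgitant fraction (%) over the full cycle.

    Forward and retrograde volumes are obtained by trapezoidal integration of
    the flow split by sign; RF = 100 · retrograde / forward. The retrograde
    volume lumps closing and leakage flow together.
    """
    c0, c1 = seg.cycle_bounds[0] if seg.cycle_bounds else (0, w.q.size)
    q = w.q[c0:c1]
    forward = float(np.trapezoid(np.clip(q, 0.0, None), dx=w.dt))
    retro = float(np.trapezoid(np.clip(-q, 0.0, None), dx=w.dt))
    if forward <= 0:
        raise DataError("zero forward volume; RF undefined")
    return 100.0 * retro / forward


def compute_eoa(
    q_rms: float, delta_p: float, fluid: FluidProperties | None = None
) -> float:
    """Effective orifice area (cm²) from Q_RMS (mL/s) and ΔP (mmHg)."""
    if fluid is None:
        fluid = FluidProperties()
    if delta_p <= 0:
        raise DomainError("delta_p must be positive to evaluate EOA")
    return q_rms / (EOA_CONSTANT * np.sqrt(delta_p / fluid.density_g_cm3))


def compute_reynolds(
    velocity: float, diameter: float, fluid: FluidProperties | None = None
) -> float:
    """Reynolds number Re = ρ·v·D/μ with v in m/s, D in m."""
    if fluid is None:
        fluid = FluidProperties()
    if velocity < 0:
        raise DomainError("velocity must be nonnegative")
    if diameter <= 0:
        raise DomainError("diameter must be positive")
    return fluid.density * velocity * diameter / fluid.viscosity_pa_s


def analyze_waveform(
    w: PressureFlowWaveform,
    n_cycles: int = 10,
    fluid: FluidProperties | None = None,
) -> HydrodynamicMetrics:
    """Full metric pipeline: ensemble-average, segment, compute RF/ΔP/Q_RMS/EOA."""
    avg = ensemble_average(w, n_cycles=n_cycles)
    seg = detect_forward_flow(avg)
    delta_p = compute_delta_p(avg, seg)
    q_rms = compute_qrms(avg, seg)
    rf = compute_rf(avg, seg)
    eoa = compute_eoa(q_rms, delta_p, fluid)
    return HydrodynamicMetrics(rf=rf, delta_p=delta_p, q_rms=q_rms, eoa=eoa)
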