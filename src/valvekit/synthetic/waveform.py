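"""Synthetic pulse-duplicator pressure/flow waveforms.

The flow pulse is a half-sine over the systolic window scaled to deliver the
configured stroke volume, followed by a brief negative closing spike (a fixed
fraction of the cycle) and a constant diastolic leakage. Aortic pressure is a
systolic pressure pulse superposed on the mean arterial pressure with the
pulse shape de-meaned on the sample grid, so the time average equals MAP
exactly before noise. Ventricular pressure sits above aortic by a half-sine
differential during systole and drops to a low filling pressure in diastole.

Defaults emulate the bench conditions of a saline pulse-duplicator run on an
uncalcified tri-leaflet scaffold valve: 70 bpm, MAP 100 mmHg, 35% systole,
and a stroke volume / closing / leakage combination giving Q_RMS ≈ 127 mL/s,
mean systolic ΔP ≈ 6.4 mmHg and RF ≈ 10.8%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ParameterError
from ..hydrodynamics import PressureFlowWaveform

__all__ = ["WaveformParams", "gen_pulse_waveform"]

#: fraction of the cycle occupied by the closing (negative) spike
CLOSING_WINDOW_FRACTION = 0.05


@dataclass
class WaveformParams:
    heart_rate: float = 70.0  # beats/min
    mean_arterial_pressure: float = 100.0  # mmHg
    systolic_fraction: float = 0.35
    stroke_volume: float = 34.4  # mL forward volume per cycle
    closing_volume_fraction: float = 0.07  # of stroke volume
    leakage_rate: float = 2.57  # mL/s during diastole
    sampling_rate: float = 1000.0  # Hz
    n_cycles: int = 10
    noise_sd_pressure: float = 0.5  # mmHg
    noise_sd_flow: float = 2.0  # mL/s
    seed: int = 0
    # shape parameters beyond the study-level settings
    systolic_dp_peak: float = 10.02  # mmHg, peak ventricular-aortic differential
    pulse_pressure: float = 20.0  # mmHg, aortic pulse amplitude
    diastolic_ventricular_pressure: float = 10.0  # mmHg

    def validate(self) -> None:
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ParameterError("systolic_fraction must lie in (0, 1)")
        if self.stroke_volume <= 0:
            raise ParameterError("stroke_volume must be positive")
        if self.closing_volume_fraction < 0:
            raise ParameterError("closing_volume_fraction must be >= 0")
        if self.leakage_rate < 0:
            raise ParameterError("leakage_rate must be >= 0")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.noise_sd_pressure < 0 or self.noise_sd_flow < 0:
            raise ParameterError("noise_sd_pressure/noise_sd_flow must be >= 0")
        if self.sampling_rate * 60.0 / self.heart_rate < 50:
            raise ParameterError(
                "sampling_rate too low: need >= 50 samples per cycle"
            )


def gen_pulse_waveform(params: WaveformParams) -> tuple[PressureFlowWaveform, dict]:
    """Generate a multi-cycle pressure/flow recording plus its ground truth.

    Returns ``(waveform, truth)`` where ``truth`` carries the analytic cycle
    quantities (forward/closing/leakage volumes, RF, mean ΔP, Q_RMS, period).
    The cycle period is snapped to the sample grid so cycles tile exactly.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)

    spc = int(round(p.sampling_rate * 60.0 / p.heart_rate))
    dt = 1.0 / p.sampling_rate
    T = spc * dt
    t = np.arange(spc) * dt

    Ts = p.systolic_fraction * T
    Tc = CLOSING_WINDOW_FRACTION * T
    Td = T - Ts - Tc  # leakage window

    q = np.zeros(spc)
    sys_mask = t < Ts
    q[sys_mask] = np.pi * p.stroke_volume / (2.0 * Ts) * np.sin(np.pi * t[sys_mask] / Ts)
    closing_volume = p.closing_volume_fraction * p.stroke_volume
    close_mask = (t >= Ts) & (t < Ts + Tc)
    q[close_mask] = -np.pi * closing_volume / (2.0 * Tc) * np.sin(
        np.pi * (t[close_mask] - Ts) / Tc
    )
    leak_mask = t >= Ts + Tc
    q[leak_mask] = -p.leakage_rate

    # aortic pressure: systolic bump de-meaned on the grid, riding on MAP
    shape = np.where(sys_mask, np.sin(np.pi * t / np.maximum(Ts, dt)), 0.0)
    p_ao = p.mean_arterial_pressure + p.pulse_pressure * (shape - shape.mean())

    dp = p.systolic_dp_peak * shape
    p_vent = np.where(sys_mask, p_ao + dp, p.diastolic_ventricular_pressure)

    tile = lambda x: np.tile(x, p.n_cycles)
    q_all = tile(q) + rng.normal(0.0, p.noise_sd_flow, spc * p.n_cycles)
    pv_all = tile(p_vent) + rng.normal(0.0, p.noise_sd_pressure, spc * p.n_cycles)
    pa_all = tile(p_ao) + rng.normal(0.0, p.noise_sd_pressure, spc * p.n_cycles)
    if p.noise_sd_flow == 0:
        q_all = tile(q)
    if p.noise_sd_pressure == 0:
        pv_all, pa_all = tile(p_vent), tile(p_ao)

    waveform = PressureFlowWaveform(
        time=np.arange(spc * p.n_cycles) * dt,
        p_vent=pv_all,
        p_ao=pa_all,
        q=q_all,
        cycle_period=T,
    )
    leakage_volume = p.leakage_rate * Td
    forward = p.stroke_volume
    truth = {
        "cycle_period_s": T,
        "systole_duration_s": Ts,
        "forward_volume_ml": forward,
        "closing_volume_ml": closing_volume,
        "leakage_volume_ml": leakage_volume,
        "net_stroke_output_ml": forward - closing_volume - leakage_volume,
        "rf_percent": 100.0 * (closing_volume + leakage_volume) / forward,
        "delta_p_mean_mmhg": 2.0 * p.systolic_dp_peak / np.pi,
        "q_rms_mls": np.pi * p.stroke_volume / (2.0 * Ts) / np.sqrt(2.0),
        "map_mmhg": p.mean_arterial_pressure,
    }
    return waveform, truth
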