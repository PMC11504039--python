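"""Synthetic nanoindentation load–displacement records.

The record mimics a flat-probe indentation protocol on soft tissue: a loading
ramp to ``max_depth`` at ``loading_rate``, an unloading ramp back to contact at
the same rate, and a faster retraction phase that pulls the probe below the
contact point. Loads on the loading/unloading ramps follow the Hertz model;
below contact the load is zero. Gaussian noise is added to the load channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ParameterError
from ..nanoindentation import IndentationRecord, hertz_load

__all__ = ["IndentationParams", "gen_indentation_record"]


@dataclass
class IndentationParams:
    youngs_modulus: float = 55.10  # kPa
    indenter_dimension_R: float = 500.0  # μm
    poisson_ratio: float = 0.30
    max_depth: float = 40.0  # μm
    loading_rate: float = 2.0  # μm/s
    retraction_rate: float = 5.0  # μm/s
    retraction_duration: float = 5.0  # s
    noise_sd: float = 0.0  # μN
    seed: int = 0
    sampling_rate: float = 50.0  # Hz
    pre_contact_um: float = 0.0  # approach travel before contact

    def validate(self) -> None:
        if self.youngs_modulus <= 0:
            raise ParameterError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ParameterError("poisson_ratio must lie in [0, 0.5)")
        if self.indenter_dimension_R <= 0:
            raise ParameterError("indenter_dimension_R must be positive")
        if self.max_depth <= 0:
            raise ParameterError("max_depth must be positive")
        if self.loading_rate <= 0 or self.retraction_rate <= 0:
            raise ParameterError("loading_rate/retraction_rate must be positive")
        if self.retraction_duration <= 0:
            raise ParameterError("retraction_duration must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.pre_contact_um < 0:
            raise ParameterError("pre_contact_um must be >= 0")


def gen_indentation_record(params: IndentationParams) -> tuple[IndentationRecord, dict]:
    """Generate one labeled indentation record plus its ground truth."""
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / p.sampling_rate

    t_appr = p.pre_contact_um / p.loading_rate
    t_load = p.max_depth / p.loading_rate
    n_appr = int(round(t_appr / dt))
    n_load = int(round(t_load / dt))
    n_unload = n_load
    n_retr = int(round(p.retraction_duration / dt))

    # displacement = probe position; contact is at pre_contact_um
    d_appr = np.arange(n_appr) * dt * p.loading_rate
    d_load = p.pre_contact_um + np.arange(n_load + 1) * dt * p.loading_rate
    d_unload = d_load[-1] - np.arange(1, n_unload + 1) * dt * p.loading_rate
    d_retr = d_unload[-1] - np.arange(1, n_retr + 1) * dt * p.retraction_rate

    displacement = np.concatenate([d_appr, d_load, d_unload, d_retr])
    labels = np.concatenate(
        [
            np.repeat("approach", n_appr),
            np.repeat("loading", n_load + 1),
            np.repeat("unloading", n_unload),
            np.repeat("retraction", n_retr),
        ]
    ).astype(object)
    time = np.arange(displacement.size) * dt

    depth = displacement - p.pre_contact_um
    load = hertz_load(
        depth, E=p.youngs_modulus, R=p.indenter_dimension_R, nu=p.poisson_ratio
    )
    load = np.asarray(load, dtype=float)
    load[labels == "retraction"] = 0.0  # probe detached
    if p.noise_sd > 0:
        load = load + rng.normal(0.0, p.noise_sd, load.size)

    record = IndentationRecord(
        time=time, displacement=displacement, load=load, segment_labels=labels
    )
    peak = hertz_load(
        p.max_depth, E=p.youngs_modulus, R=p.indenter_dimension_R, nu=p.poisson_ratio
    )
    truth = {
        "youngs_modulus_kpa": p.youngs_modulus,
        "contact_offset_um": p.pre_contact_um,
        "peak_load_un": float(peak),
        "segments": {
            "approach": n_appr,
            "loading": n_load + 1,
            "unloading": n_unload,
            "retraction": n_retr,
        },
    }
    return record, truth
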