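"""Hertzian contact analysis of nanoindentation load–displacement records.

A flat-ended probe of characteristic dimension R indents a soft tissue sample;
during the loading phase the load is modeled as

    P = 4 E sqrt(R) δ^{3/2} / (3 (1 − ν²))

with P the load, δ the indentation depth past contact, E Young's modulus and ν
the Poisson ratio. Working units are μN, μm and kPa (kPa·μm² = 1e-3 μN, which
is folded into the prefactor). Only the loading segment is fitted; the model is
linear in E once δ^{3/2} is known, so the fit reduces to a one-parameter least
squares, optionally combined with a grid search over the contact offset δ₀.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError, EstimationError

__all__ = [
    "IndentationRecord",
    "HertzFitResult",
    "hertz_load",
    "split_segments",
    "detect_contact_point",
    "fit_hertz",
]

SEGMENT_NAMES = ("loading", "unloading", "retraction")

# kPa · μm^2 -> μN
_UNIT_FACTOR = 1e-3


@dataclass
class IndentationRecord:
    """One indentation measurement: time (s), displacement (μm), load (μN).

    ``segment_labels`` holds one of {"approach", "loading", "unloading",
    "retraction"} per sample ("approach" covers pre-contact travel).
    """

    time: np.ndarray
    displacement: np.ndarray
    load: np.ndarray
    segment_labels: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels, dtype=object)
        n = self.time.size
        if not (self.displacement.size == self.load.size == self.segment_labels.size == n):
            raise DataError("record channels must have equal length")

    def segment(self, name: str) -> np.ndarray:
        """Boolean mask of the samples labeled ``name``."""
        return self.segment_labels == name


@dataclass
class HertzFitResult:
    youngs_modulus: float  # kPa
    contact_offset: float  # μm
    rss: float  # μN²
    n_points: int
    indenter_R: float  # μm
    poisson: float


def hertz_load(delta, E: float, R: float = 500.0, nu: float = 0.30):
    """Hertz-model load (μN) at indentation depth ``delta`` (μm).

    Negative depths (pre-contact) map to zero load. E in kPa, R in μm.
    """
    if nu >= 1.0:
        raise DomainError("poisson ratio must be < 1")
    if E <= 0:
        raise DomainError("youngs modulus must be positive")
    if R <= 0:
        raise DomainError("indenter dimension R must be positive")
    d = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    P = 4.0 * E * np.sqrt(R) * d**1.5 / (3.0 * (1.0 - nu**2)) * _UNIT_FACTOR
    return P if P.ndim else float(P)


def split_segments(
    time, displacement, load, rate_split_factor: float = 1.5
) -> IndentationRecord:
    """Label a raw record into loading / unloading / retraction phases.

    Phases are found from the sign of the displacement rate: the initial
    positive-rate run is loading; the subsequent negative-rate run is split
    into unloading and retraction where the rate magnitude jumps above
    ``rate_split_factor`` times the initial unloading rate (the retraction
    phase is driven faster than the unloading ramp).
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(displacement, dtype=float)
    p = np.asarray(load, dtype=float)
    if t.size < 3:
        raise DataError("record too short to segment")
    rate = np.gradient(d, t)
    pos = rate > 0
    if not pos[0] and not np.any(pos):
        raise DataError("no monotone loading phase found")
    first_pos = int(np.argmax(pos))
    after = pos[first_pos:]
    load_end = first_pos + (int(np.argmin(after)) if not after.all() else after.size)
    labels = np.empty(t.size, dtype=object)
    labels[:first_pos] = "approach"
    labels[first_pos:load_end] = "loading"
    if load_end < t.size:
        neg_rate = -rate[load_end:]
        base = np.median(neg_rate[: max(3, neg_rate.size // 4)])
        fast = neg_rate > rate_split_factor * max(base, 1e-12)
        retr_start = load_end + (int(np.argmax(fast)) if np.any(fast) else neg_rate.size)
        labels[load_end:retr_start] = "unloading"
        labels[retr_start:] = "retraction"
    return IndentationRecord(time=t, displacement=d, load=p, segment_labels=labels)


def _linear_E(delta: np.ndarray, load: np.ndarray, R: float, nu: float) -> tuple[float, float]:
    """Closed-form least-squares E (kPa) and RSS for known contact offset."""
    x = 4.0 * np.sqrt(R) * np.clip(delta, 0.0, None) ** 1.5 / (3.0 * (1.0 - nu**2)) * _UNIT_FACTOR
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        raise EstimationError("degenerate loading segment (no indentation depth)")
    E = float(np.dot(x, load)) / sxx
    rss = float(np.sum((load - E * x) ** 2))
    return E, rss


def detect_contact_point(
    displacement,
    load,
    R: float = 500.0,
    nu: float = 0.30,
    n_grid: int = 81,
) -> float:
    """Estimate the contact offset δ₀ (μm) of a loading segment.

    Grid-searches δ₀ jointly with the closed-form linear-in-E fit of the Hertz
    model on (δ − δ₀)⁺ and returns the offset minimizing the residual sum of
    squares, refined once on a finer local grid.
    """
    d = np.asarray(displacement, dtype=float)
    p = np.asarray(load, dtype=float)
    if d.size < 10:
        raise DataError("need at least 10 loading samples for contact detection")
    if np.all(p <= 0) or float(np.max(p)) <= 0:
        raise EstimationError("no positive load; cannot locate contact")

    span = float(d.max() - d.min())
    if span <= 0:
        raise EstimationError("displacement does not advance")

    def best_on(grid: np.ndarray) -> tuple[float, float]:
        rss_best, off_best = np.inf, grid[0]
        for off in grid:
            depth = d - off
            if np.count_nonzero(depth > 0) < 5:
                continue
            try:
                E, rss = _linear_E(depth, p, R, nu)
            except EstimationError:
                continue
            if E > 0 and rss < rss_best:
                rss_best, off_best = rss, off
        if not np.isfinite(rss_best):
            raise EstimationError("contact-point search failed to converge")
        return float(off_best), rss_best

    coarse = np.linspace(d.min(), d.min() + 0.75 * span, n_grid)
    off, _ = best_on(coarse)
    step = coarse[1] - coarse[0]
    fine = np.linspace(off - step, off + step, 41)
    off, _ = best_on(fine)
    return off


def fit_hertz(
    record: IndentationRecord,
    R: float = 500.0,
    nu: float = 0.30,
    segment: str = "loading",
    fit_offset: bool = False,
) -> HertzFitResult:
    """Least-squares Hertz fit of Young's modulus on the loading segment.

    The model is fitted to the loading phase only; requesting any other
    segment raises :class:`DomainError`. With ``fit_offset=True`` the contact
    offset δ₀ is estimated jointly (grid search), otherwise δ₀ = 0.
    """
    if segment != "loading":
        raise DomainError("Hertz fit is defined on the loading segment only")
    if nu >= 1.0:
        raise DomainError("poisson ratio must be < 1")
    mask = record.segment("loading")
    d = record.displacement[mask]
    p = record.load[mask]
    if d.size < 5:
        raise DataError("loading segment must hold at least 5 samples")
    if np.any(np.diff(d) < -1e-9):
        raise DataError("loading segment displacement must be nondecreasing")
    offset = detect_contact_point(d, p, R=R, nu=nu) if fit_offset else 0.0
    E, rss = _linear_E(d - offset, p, R, nu)
    if E <= 0:
        raise EstimationError(f"fit produced nonpositive modulus E={E:.3g} kPa")
    return HertzFitResult(
        youngs_modulus=E,
        contact_offset=offset,
        rss=rss,
        n_points=int(d.size),
        indenter_R=R,
        poisson=nu,
    )
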