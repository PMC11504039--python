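"""Group comparison statistics and in vitro / in silico validation tables.

Three experimental groups (raw, static, bioreactor) are compared per metric
with a normality screen (D'Agostino–Pearson skewness/kurtosis omnibus test)
followed by unpaired Student's t-tests, with tiered significance markers at
p < 0.05 / 0.01 / 0.001 / 0.0001. Validation tables pair an in vitro and an
in silico value per metric and report the symmetric percent difference

    %Δ = 100 · |v₁ − v₂| / ((v₁ + v₂) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DomainError

__all__ = [
    "SampleGroup",
    "TestResult",
    "ComparisonRow",
    "percent_difference",
    "significance_tier",
    "normality_test",
    "unpaired_t_test",
    "build_comparison_table",
]

TIER_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

#: minimum n for the omnibus normality test to be meaningful
NORMALITY_MIN_N = 8


@dataclass
class SampleGroup:
    label: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise DataError(f"group {self.label!r} needs at least 2 values")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"group {self.label!r} contains non-finite values")


@dataclass
class TestResult:
    statistic: float | None
    p_value: float | None
    tier: str
    note: str = ""


@dataclass
class ComparisonRow:
    metric_name: str
    group: str
    in_vitro: float
    in_silico: float
    percent_diff: float = field(init=False)

    def __post_init__(self) -> None:
        self.percent_diff = percent_difference(self.in_vitro, self.in_silico)


def percent_difference(v1: float, v2: float) -> float:
    """Symmetric percent difference 100·|v1−v2|/mean(v1,v2)."""
    mean = (v1 + v2) / 2.0
    if mean == 0:
        raise DomainError("percent difference undefined when v1 + v2 = 0")
    return 100.0 * abs(v1 - v2) / abs(mean)


def significance_tier(p: float) -> str:
    """Map a p-value to the tiered marker convention (n.s., *, **, ***, ****)."""
    if not 0.0 <= p <= 1.0:
        raise DomainError("p-value must lie in [0, 1]")
    for threshold, marker in TIER_THRESHOLDS:
        if p < threshold:
            return marker
    return "n.s."


def normality_test(group: SampleGroup) -> TestResult:
    """Skewness/kurtosis (D'Agostino–Pearson K²) omnibus normality test.

    Samples smaller than ``NORMALITY_MIN_N`` return a warning result with no
    p-value rather than an unreliable omnibus statistic.
    """
    x = group.values
    if np.ptp(x) == 0:
        raise DataError(f"group {group.label!r} is constant; normality undefined")
    if x.size < NORMALITY_MIN_N:
        return TestResult(
            statistic=None,
            p_value=None,
            tier="n/a",
            note=f"n={x.size} < {NORMALITY_MIN_N}: omnibus normality test skipped",
        )
    k2, p = sps.normaltest(x)
    return TestResult(statistic=float(k2), p_value=float(p), tier=significance_tier(float(p)))


def unpaired_t_test(
    a: SampleGroup, b: SampleGroup, equal_var: bool = True
) -> TestResult:
    """Two-sided unpaired Student's t-test (pooled variance by default).

    ``equal_var=False`` switches to the Welch variant.
    """
    if np.var(a.values, ddof=1) + np.var(b.values, ddof=1) == 0:
        if np.mean(a.values) == np.mean(b.values):
            return TestResult(statistic=0.0, p_value=1.0, tier="n.s.")
        raise DataError("zero pooled variance with unequal means; t undefined")
    t, p = sps.ttest_ind(a.values, b.values, equal_var=equal_var)
    return TestResult(statistic=float(t), p_value=float(p), tier=significance_tier(float(p)))


def build_comparison_table(in_vitro: dict, in_silico: dict) -> pd.DataFrame:
    """Pair per-group in vitro / in silico metric maps into a %Δ table.

    Both arguments map ``group -> {metric -> value}`` (or ``metric -> value``
    directly for a single unnamed group). Returns a DataFrame with columns
    metric, group, in_vitro, in_silico, percent_diff.
    """

    def normalize(d: dict) -> dict:
        if d and not isinstance(next(iter(d.values())), dict):
            return {"": dict(d)}
        return {g: dict(m) for g, m in d.items()}

    vitro, silico = normalize(in_vitro), normalize(in_silico)
    missing = []
    for g in sorted(set(vitro) | set(silico)):
        if g not in vitro or g not in silico:
            missing.append(f"group {g!r}")
            continue
        for key in sorted(set(vitro[g]) ^ set(silico[g])):
            missing.append(f"{g}/{key}")
    if missing:
        raise DataError("mismatched comparison keys: " + ", ".join(missing))
    rows = [
        ComparisonRow(metric_name=m, group=g, in_vitro=vitro[g][m], in_silico=silico[g][m])
        for g in vitro
        for m in vitro[g]
    ]
    return pd.DataFrame(
        [
            {
                "metric": r.metric_name,
                "group": r.group,
                "in_vitro": r.in_vitro,
                "in_silico": r.in_silico,
                "percent_diff": r.percent_diff,
            }
            for r in rows
        ]
    )
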