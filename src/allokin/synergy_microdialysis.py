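"""Paired-inhibitor synergy arithmetic and microdialysis time-course transforms.

Synergy is scored against Bliss independence: two inhibitors acting through
independent mechanisms leave a fraction f_a·f_b of activity; observed
remaining activity below that product indicates synergy.  Microdialysis
traces (20-min dialysate fractions) are expressed as percent of the mean
pre-perfusion baseline, summarized as area under the curve above baseline
over the perfusion window, and perfusate concentrations are corrected for
probe membrane recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DialysisSeries",
    "bliss_expected",
    "synergy_excess",
    "percent_of_basal",
    "auc_window",
    "probe_recovery_correct",
]


@dataclass
class DialysisSeries:
    """Dialysate fraction series: times (min, fraction end times), analyte
    values, and the count of pre-perfusion (basal) fractions at the start."""

    times: np.ndarray
    values: np.ndarray
    n_basal: int = 3

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")
        if self.n_basal < 1:
            raise ValueError("need at least one basal fraction")
        if self.times.size < self.n_basal + 1:
            raise ValueError("series must extend beyond the basal fractions")


def bliss_expected(f_a: float, f_b: float) -> float:
    """Expected remaining fractional activity under independent inhibitors: f_a·f_b."""
    for name, v in (("f_a", f_a), ("f_b", f_b)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return f_a * f_b


def synergy_excess(f_observed: float, f_expected: float) -> float:
    """Excess inhibition beyond independence: f_expected − f_observed.

    Positive values mean the combination removed more activity than the
    Bliss product predicts (synergy); negative values point to antagonism.
    """
    for name, v in (("f_observed", f_observed), ("f_expected", f_expected)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return f_expected - f_observed


def percent_of_basal(series: DialysisSeries) -> np.ndarray:
    """Express each fraction as percent of the mean of the first ``n_basal``
    (pre-perfusion) fractions."""
    basal = float(series.values[: series.n_basal].mean())
    if basal <= 0:
        raise ValueError("basal mean must be positive")
    return series.values * 100.0 / basal


def auc_window(
    times: np.ndarray,
    percent: np.ndarray,
    window: tuple[float, float] = (20.0, 160.0),
    baseline: float = 100.0,
) -> float:
    """Trapezoidal area of (percent − baseline) over ``window`` (%·min).

    Window endpoints must lie inside the sampled range; values at the
    endpoints are obtained by linear interpolation when they fall between
    fractions.  The default subtracts the 100% basal level, so the area
    measures release above baseline.
    """
    times = np.asarray(times, dtype=float)
    percent = np.asarray(percent, dtype=float)
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be an increasing (start, end) pair")
    if lo < times[0] or hi > times[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] lies outside the sampled range "
            f"[{times[0]}, {times[-1]}]"
        )
    inside = (times > lo) & (times < hi)
    t = np.concatenate(([lo], times[inside], [hi]))
    y = np.concatenate((
        [np.interp(lo, times, percent)],
        percent[inside],
        [np.interp(hi, times, percent)],
    ))
    return float(np.trapezoid(y - baseline, t))


def probe_recovery_correct(perfusate_conc: float, recovery_fraction: float) -> float:
    """Effective tissue-side concentration: perfusate × probe recovery fraction."""
    if not 0 < recovery_fraction <= 1:
        raise ValueError(
            f"recovery fraction must lie in (0, 1], got {recovery_fraction}"
        )
    if perfusate_conc < 0:
        raise ValueError("perfusate concentration must be nonnegative")
    return perfusate_conc * recovery_fraction
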