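"""Allosteric potency: normalized rate ratios, pIC50 fitting, intervals, ΔAP.

The headline statistic of the dissociation assay.  Per-drug dissociation rate
constants are normalized to the buffer control (k_drug/k_buffer); the
resulting ratio-vs-log-concentration curve is fit with a logistic whose
midpoint is parametrized as pIC50 = −log10(IC50 in molar), so standard
errors live on the log scale and concentration intervals
10^(9−(pIC50±SE)) nM are asymmetric, matching the convention of reporting
"IC50 [lo; hi]".  Fold changes in potency between constructs (ΔAP =
IC50_mut/IC50_wt) support censored lower bounds for mutants whose potency
exceeds the tested range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "PotencyFit",
    "FoldChange",
    "normalize_rates",
    "fit_allosteric_ic50",
    "interval_from_pic50",
    "delta_ap",
]


@dataclass
class DoseResponseCurve:
    """Concentrations (nM) with dimensionless responses (rate ratios for the
    dissociation assay, raw signals for competition binding) and optional
    per-point weights (1/SD²)."""

    concentrations: np.ndarray
    ratios: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.concentrations.shape != self.ratios.shape:
            raise ValueError("concentrations and ratios must have equal length")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.ratios.shape:
                raise ValueError("weights must match ratios in length")


@dataclass
class PotencyFit:
    """pIC50-parametrized logistic fit: point estimate, SE, concentration-scale
    IC50 with asymmetric ±SE interval, curve span, convergence flag."""

    pic50: float
    se_pic50: float
    ic50_nM: float
    interval_nM: tuple[float, float]
    span: tuple[float, float]
    converged: bool
    hill: float = 1.0


@dataclass(frozen=True)
class FoldChange:
    """ΔAP fold change; ``censored`` marks a lower bound (mutant IC50 itself a
    lower bound), in which case the true fold change exceeds ``value``."""

    value: float
    censored: bool = False

    @property
    def bound_direction(self) -> str:
        return "lower" if self.censored else "none"

    @property
    def rounded(self) -> float:
        """Table-style reporting precision: integer for values ≥ 10, one
        decimal below 10."""
        return float(round(self.value)) if self.value >= 10 else round(self.value, 1)


def normalize_rates(rate_table: pd.DataFrame, k_buffer: float | None = None) -> DoseResponseCurve:
    """Normalize a per-replicate rate table to the buffer control.

    ``rate_table`` needs columns ``conc_nM`` and ``k_per_min``.  If
    ``k_buffer`` is not given it is the mean rate over the c = 0 rows (their
    absence is an error).  Replicate ratios are averaged per concentration;
    when ≥3 replicates exist, 1/SD² of the replicate ratios is retained as
    the fit weight.
    """
    if k_buffer is None:
        ctrl = rate_table.loc[rate_table["conc_nM"] == 0, "k_per_min"]
        if ctrl.empty:
            raise ValueError("rate table has no buffer control (conc_nM == 0) "
                             "and no k_buffer was supplied")
        k_buffer = float(ctrl.mean())
    if k_buffer <= 0:
        raise ValueError("k_buffer must be positive")

    tab = rate_table.copy()
    tab["ratio"] = tab["k_per_min"] / k_buffer
    g = tab.groupby("conc_nM")["ratio"]
    mean = g.mean()
    sd = g.std(ddof=1)
    n = g.size()
    concs = mean.index.to_numpy(dtype=float)
    ratios = mean.to_numpy(dtype=float)
    weights = np.ones_like(ratios)
    usable = (n.to_numpy() >= 3) & (np.nan_to_num(sd.to_numpy()) > 0)
    if usable.all():
        weights = 1.0 / sd.to_numpy() ** 2
        # few-replicate SDs are noisy; keep weights within a decade of the
        # median so no single concentration can dominate the fit
        med = np.median(weights)
        weights = np.clip(weights, med / 10.0, med * 10.0)
    return DoseResponseCurve(concentrations=concs, ratios=ratios, weights=weights)


def _logistic(c, pic50, top, bottom, hill):
    # c in nM; pIC50 on the molar scale
    log_c_molar = np.where(c > 0, np.log10(np.where(c > 0, c, 1.0)) - 9.0, -np.inf)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c_molar + pic50)))


def fit_allosteric_ic50(
    curve: DoseResponseCurve,
    top: float | None = 1.0,
    bottom: float | None = 0.0,
    hill: float | None = 1.0,
    flat_span: float = 0.1,
) -> PotencyFit:
    """Fit the normalized-ratio curve as a logistic in log concentration.

    ``top``, ``bottom`` and ``hill`` are fixed at the given values; pass
    ``None`` to free any of them (competition binding frees top/bottom).
    The optimized location parameter is pIC50, so ``se_pic50`` comes straight
    from the fit covariance.  A flat curve (response span below ``flat_span``)
    is returned with ``converged=False`` instead of a spurious estimate.
    """
    c = curve.concentrations
    y = curve.ratios
    if np.all(c == 0):
        raise ValueError("all concentrations are zero; nothing to fit")
    if np.unique(c[c > 0]).size < 4:
        raise ValueError("need at least 4 distinct nonzero concentrations")
    w = np.sqrt(curve.weights) if curve.weights is not None else np.ones_like(y)

    span = float(y.max() - y.min())
    mid_guess = float(np.median(np.log10(c[c > 0]))) - 9.0

    if span < flat_span:
        return PotencyFit(
            pic50=-mid_guess, se_pic50=math.nan, ic50_nM=10 ** (9 + mid_guess),
            interval_nM=(math.nan, math.nan), span=(y.max(), y.min()),
            converged=False,
        )

    free: list[str] = ["pic50"]
    fixed = {"top": top, "bottom": bottom, "hill": hill}
    for name, v in fixed.items():
        if v is None:
            free.append(name)
    init = {"pic50": -mid_guess, "top": float(y.max()), "bottom": max(float(y.min()), 0.0),
            "hill": 1.0}

    def unpack(p):
        vals = dict(fixed)
        for name, v in zip(free, p):
            vals[name] = v
        return vals

    def resid(p):
        v = unpack(p)
        return w * (_logistic(c, v["pic50"], v["top"], v["bottom"], v["hill"]) - y)

    p0 = np.array([init[name] for name in free])
    lb = np.array([-np.inf if f == "pic50" else (0.0 if f in ("bottom", "hill") else -np.inf)
                   for f in free])
    ub = np.full(len(free), np.inf)
    sol = least_squares(resid, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=None)
    v = unpack(sol.x)
    pic50 = float(v["pic50"])
    ic50 = 10.0 ** (9.0 - pic50)

    dof = y.size - len(free)
    se = math.nan
    if dof > 0:
        ss = float(np.sum(sol.fun**2))
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (ss / dof)
            se = float(math.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            pass

    # a fit drifting outside the tested range by >2 decades is not an estimate
    in_range = (
        math.log10(c[c > 0].min()) - 2 <= 9 - pic50 if c[c > 0].size else True
    ) and (9 - pic50 <= math.log10(c.max()) + 2)
    ok = bool(sol.success) and in_range
    lo, hi = interval_from_pic50(pic50, se) if math.isfinite(se) else (math.nan, math.nan)
    return PotencyFit(
        pic50=pic50, se_pic50=se, ic50_nM=ic50, interval_nM=(lo, hi),
        span=(float(v["top"]), float(v["bottom"])), converged=ok,
        hill=float(v["hill"]),
    )


def interval_from_pic50(pic50: float, se: float) -> tuple[float, float]:
    """Asymmetric nM interval from pIC50 ± SE: (10^(9−(pIC50+SE)), 10^(9−(pIC50−SE)))."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    return 10.0 ** (9.0 - (pic50 + se)), 10.0 ** (9.0 - (pic50 - se))


def delta_ap(ic50_mut: float, ic50_wt: float, mut_censored: bool = False) -> FoldChange:
    """Fold change in allosteric potency of a mutant relative to wild type.

    ``mut_censored=True`` marks the mutant IC50 as a lower bound (potency
    ablated beyond the tested range); the fold change is then itself a lower
    bound.
    """
    if ic50_mut <= 0 or ic50_wt <= 0:
        raise ValueError("IC50 values must be positive")
    return FoldChange(value=ic50_mut / ic50_wt, censored=mut_censored)
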