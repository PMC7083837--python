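"""Extraction of first-order dissociation rate constants from time courses.

Fitting is two-stage: a log-linear regression of log(signal) on time supplies
starting values, then a nonlinear least-squares refinement of
``ns + b0·exp(−k·t)``.  The plateau term ``ns`` is fixed at 0 by default
because the assay subtracts nonspecific binding by design; pass
``with_plateau=True`` to free it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .binding_models import TimeCourse

__all__ = ["RateEstimate", "fit_monoexponential", "half_life", "fit_rate_table"]

#: relative parameter-change tolerance of the nonlinear refinement
XTOL = 1e-10
MAX_ITER = 500


@dataclass
class RateEstimate:
    """Monoexponential fit result: rate constant k (min⁻¹), amplitude b0,
    optional plateau, standard error of k and goodness of fit."""

    k: float
    b0: float
    ns_plateau: float | None
    se_k: float
    r_squared: float
    converged: bool = True


def _loglinear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # slope of log y on t gives -k; intercept gives log b0
    slope, intercept = np.polyfit(t, np.log(y), 1)
    k0 = max(-slope, 1e-12)
    return k0, math.exp(intercept)


def fit_monoexponential(
    tc: TimeCourse, with_plateau: bool = False, weighting: str = "relative"
) -> RateEstimate:
    """Fit ``ns + b0·exp(−k·t)`` to one time course.

    Requires at least 3 time points (4 with plateau).  Without a plateau all
    signals must be strictly positive so the log-linear initialization is
    defined.  ``weighting="relative"`` (default) minimizes relative
    residuals — the appropriate objective for scintillation counts, whose
    error scales with the signal — and makes ``se_k`` honestly calibrated
    under proportional noise; ``"none"`` gives plain unweighted least
    squares.  Non-convergence is flagged on the result rather than raised.
    """
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t = np.asarray(tc.times, dtype=float)
    y = np.asarray(tc.signals, dtype=float)
    n_par = 3 if with_plateau else 2
    if t.size < max(3, n_par + 1 if with_plateau else 3):
        raise ValueError(f"need at least {'4' if with_plateau else '3'} time points, got {t.size}")
    tiny = 1e-12 * max(float(y.max()), 1.0)

    def _weighted(raw, pred):
        if weighting == "none":
            return raw
        return raw / np.maximum(np.abs(pred), tiny)

    if not with_plateau:
        bad = np.nonzero(y <= 0)[0]
        if bad.size:
            raise ValueError(
                f"nonpositive signal at t={t[bad[0]]:g} min (index {bad[0]}); "
                "use with_plateau=True or remove the point"
            )
        k0, b00 = _loglinear_init(t, y)
        p0 = np.array([k0, b00])

        def resid(p):
            pred = p[1] * np.exp(-p[0] * t)
            return _weighted(pred - y, pred)

    else:
        floor = float(np.min(y))
        ypos = y - floor + max(1.0, 1e-3 * max(abs(floor), 1.0))
        k0, b00 = _loglinear_init(t, ypos)
        p0 = np.array([k0, b00, max(floor, 0.0)])

        def resid(p):
            pred = p[2] + p[1] * np.exp(-p[0] * t)
            return _weighted(pred - y, pred)

    lb = np.zeros(n_par)
    ub = np.full(n_par, np.inf)
    sol = least_squares(resid, p0, bounds=(lb, ub), xtol=XTOL, ftol=XTOL, gtol=None,
                        max_nfev=MAX_ITER * n_par)
    k = float(sol.x[0])
    b0 = float(sol.x[1])
    ns = float(sol.x[2]) if with_plateau else None

    dof = t.size - n_par
    ss_res = float(np.sum(sol.fun**2))  # in the fit's (possibly weighted) units
    pred = (ns or 0.0) + b0 * np.exp(-k * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred - y) ** 2)) / ss_tot if ss_tot > 0 else 1.0

    # SE of k from the Jacobian at the solution
    se_k = math.nan
    if dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (ss_res / dof if dof else 0.0)
            se_k = float(math.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            pass
    return RateEstimate(k=k, b0=b0, ns_plateau=ns, se_k=se_k, r_squared=r2,
                        converged=bool(sol.success))


def half_life(k: float) -> float:
    """Half-life ln2/k in minutes; requires k > 0."""
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return math.log(2.0) / k


def fit_rate_table(timecourses, with_plateau: bool = False) -> pd.DataFrame:
    """Fit each time course and return a tidy per-condition rate table with
    columns (condition, conc_nM, replicate, k_per_min, se_k, b0, r_squared)."""
    rows = []
    for tc in timecourses:
        est = fit_monoexponential(tc, with_plateau=with_plateau)
        rows.append(
            {
                "condition": tc.condition,
                "conc_nM": tc.concentration,
                "replicate": tc.replicate,
                "k_per_min": est.k,
                "se_k": est.se_k,
                "b0": est.b0,
                "r_squared": est.r_squared,
            }
        )
    return pd.DataFrame(rows)
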