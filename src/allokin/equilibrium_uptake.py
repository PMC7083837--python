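"""Equilibrium competition binding and substrate-uptake kinetics.

Covers the S1-pharmacology side of the assay battery: one-site competition
IC50 fitting, the Cheng–Prusoff conversion to Ki, Michaelis–Menten saturation
fits, a global mixed-inhibition fit across inhibitor levels, and a simple
mechanism classifier based on how apparent KM and Vmax move with inhibitor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .allosteric_potency import DoseResponseCurve, PotencyFit, fit_allosteric_ic50
from .binding_models import MixedInhibitionModel, uptake_velocity

__all__ = [
    "SaturationDataset",
    "fit_competition",
    "cheng_prusoff",
    "fit_michaelis_menten",
    "fit_mixed_inhibition",
    "classify_mechanism",
]


@dataclass
class SaturationDataset:
    """Uptake velocities over substrate concentrations at one inhibitor level."""

    substrate_concs: np.ndarray  # nM
    velocities: np.ndarray       # fmol/min
    inhibitor_conc: float = 0.0  # nM
    replicate: int = 0

    def __post_init__(self) -> None:
        self.substrate_concs = np.asarray(self.substrate_concs, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.substrate_concs.shape != self.velocities.shape:
            raise ValueError("substrate_concs and velocities must have equal length")
        if np.any(self.substrate_concs < 0) or np.any(self.velocities < 0):
            raise ValueError("concentrations and velocities must be nonnegative")
        if self.inhibitor_conc < 0:
            raise ValueError("inhibitor_conc must be nonnegative")
        if np.unique(self.substrate_concs).size < 4:
            raise ValueError("need at least 4 distinct substrate levels")


def fit_competition(curve: DoseResponseCurve) -> PotencyFit:
    """One-site competition fit with free top and bottom (bottom ≥ 0).

    Same logistic machinery as the allosteric-potency fit; flat or
    wrong-direction data come back flagged ``converged=False``.
    """
    y = curve.ratios
    span = float(y.max() - y.min())
    fit = fit_allosteric_ic50(curve, top=None, bottom=None, hill=1.0,
                              flat_span=0.1 * max(abs(float(y.max())), 1.0))
    # monotone-increasing responses: the logistic has the wrong sign; flag
    c = curve.concentrations
    order = np.argsort(c)
    if span > 0 and np.all(np.diff(y[order]) >= 0) and np.any(np.diff(y[order]) > 0):
        fit.converged = False
    return fit


def cheng_prusoff(ic50: float, radioligand_conc: float, kd: float) -> float:
    """Ki = IC50/(1 + L/KD): competition IC50 corrected for radioligand
    (or substrate) occupancy.  All arguments positive, in matching units."""
    if ic50 <= 0 or radioligand_conc <= 0 or kd <= 0:
        raise ValueError("ic50, radioligand concentration and kd must be positive")
    return ic50 / (1.0 + radioligand_conc / kd)


def _double_reciprocal_init(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    # Lineweaver–Burk on the points with positive S and v
    m = (S > 0) & (v > 0)
    if m.sum() < 2:
        return float(v.max()), float(np.median(S[S > 0])) if np.any(S > 0) else 1.0
    slope, intercept = np.polyfit(1.0 / S[m], 1.0 / v[m], 1)
    if intercept <= 0:
        return float(v.max()), float(np.median(S[S > 0]))
    vmax0 = 1.0 / intercept
    km0 = max(slope * vmax0, 1e-9)
    return vmax0, km0


def fit_michaelis_menten(dataset: SaturationDataset) -> tuple[float, float]:
    """Least-squares Michaelis–Menten fit v = Vmax·S/(KM+S).

    Initialized from a double-reciprocal regression.  Returns (Vmax, KM).
    A KM collapsing below 1e−6 of the largest substrate level (velocity flat
    in S) is flagged by raising ``RuntimeError``.
    """
    S, v = dataset.substrate_concs, dataset.velocities

    def resid(p):
        return p[0] * S / (p[1] + S) - v

    p0 = np.array(_double_reciprocal_init(S, v))
    sol = least_squares(resid, p0, bounds=(np.zeros(2), np.full(2, np.inf)),
                        xtol=1e-12, ftol=1e-12, gtol=None)
    vmax, km = float(sol.x[0]), float(sol.x[1])
    if not sol.success:
        raise RuntimeError("Michaelis–Menten fit did not converge")
    if km < 1e-6 * float(S.max()):
        raise RuntimeError(
            "KM collapsed to zero: velocity does not depend on substrate level"
        )
    return vmax, km


def fit_mixed_inhibition(datasets: list[SaturationDataset]):
    """Global mixed-inhibition fit across ≥2 inhibitor levels (0 included).

    All points share (Vmax, KM, Ki_c, Ki_u) through
    ``v = Vmax·S/(KM·(1+I/Ki_c) + S·(1+I/Ki_u))``.  Returns the fitted
    :class:`MixedInhibitionModel` plus a per-level table of apparent
    (Vmax, KM) obtained by independent Michaelis–Menten refits.
    """
    levels = sorted({d.inhibitor_conc for d in datasets})
    if len(levels) < 2:
        raise ValueError(
            "need at least two inhibitor levels including 0; "
            "for a single level use fit_michaelis_menten"
        )
    if 0.0 not in levels:
        raise ValueError("a 0-inhibitor control is required")

    S = np.concatenate([d.substrate_concs for d in datasets])
    I = np.concatenate([np.full(d.substrate_concs.size, d.inhibitor_conc) for d in datasets])
    v = np.concatenate([d.velocities for d in datasets])

    ctrl = next(d for d in datasets if d.inhibitor_conc == 0.0)
    vmax0, km0 = fit_michaelis_menten(ctrl)
    imax = max(levels)

    # inverse inhibition constants (ac=1/ki_c, au=1/ki_u) with bounds ≥ 0 so
    # that the pure-competitive limit ki_u = ∞ sits exactly on the boundary
    def resid(p):
        vmax, km, ac, au = p
        return vmax * S / (km * (1.0 + I * ac) + S * (1.0 + I * au)) - v

    p0 = np.array([vmax0, km0, 1.0 / imax, 1.0 / imax])
    sol = least_squares(resid, p0, bounds=(np.zeros(4), np.full(4, np.inf)),
                        xtol=1e-14, ftol=1e-14, gtol=None)
    vmax, km, ac, au = (float(x) for x in sol.x)
    model = MixedInhibitionModel(
        vmax=vmax, km=km,
        ki_c=(1.0 / ac if ac > 0 else math.inf),
        ki_u=(1.0 / au if au > 0 else math.inf),
    )

    apparent = []
    for d in sorted(datasets, key=lambda d: d.inhibitor_conc):
        av, ak = fit_michaelis_menten(d)
        apparent.append({"inhibitor_nM": d.inhibitor_conc, "vmax": av, "km": ak})
    return model, apparent


def classify_mechanism(apparent: list[dict], rel_tol: float = 0.1) -> str:
    """Classify inhibition from per-level apparent (Vmax, KM).

    Ordered by inhibitor level, comparing highest to zero-inhibitor control:
    KM up & Vmax flat → competitive; Vmax down & KM flat → noncompetitive;
    both moving → mixed; anything else (no change, or KM falling / Vmax
    rising) → indeterminate.  "Flat" means within ``rel_tol`` relative change.
    """
    if len(apparent) < 2:
        raise ValueError("need apparent parameters at ≥2 inhibitor levels")
    ordered = sorted(apparent, key=lambda a: a["inhibitor_nM"])
    km0, km1 = ordered[0]["km"], ordered[-1]["km"]
    v0, v1 = ordered[0]["vmax"], ordered[-1]["vmax"]
    km_up = km1 > km0 * (1 + rel_tol)
    km_flat = abs(km1 - km0) <= rel_tol * km0
    v_down = v1 < v0 * (1 - rel_tol)
    v_flat = abs(v1 - v0) <= rel_tol * v0
    if km_up and v_flat:
        return "competitive"
    if v_down and km_flat:
        return "noncompetitive"
    if km_up and v_down:
        return "mixed"
    return "indeterminate"
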