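"""Generative models for the pharmacology experiment classes.

The central object is :class:`AllostericDissociationModel`: a vestibule
(S2-site) ligand occupies the transporter's extracellular vestibule in rapid
equilibrium and suppresses the first-order dissociation rate of a radioligand
pre-bound at the central (S1) site.  The observed dissociation rate is

    k_obs(c) = k_buffer * (1 - emax * c^h / (c^h + IC50^h))

so that at ``c = IC50`` (with ``emax = 1``, ``h = 1``) the rate is halved —
the operational definition of allosteric potency.  The other model classes
cover one-site competition binding, Michaelis–Menten uptake under mixed
(competitive + uncompetitive) inhibition, and paired-inhibitor designs.

All concentrations are in nM, rates in min⁻¹ (uptake velocities in fmol/min),
times in minutes.  Simulators are deterministic given a seed: per-curve
substreams are derived from (seed, condition index, replicate index) so that
adding a condition never reshuffles the noise of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AllostericDissociationModel",
    "DissociationDesign",
    "TimeCourse",
    "CompetitionModel",
    "MixedInhibitionModel",
    "SynergyDesign",
    "k_obs",
    "simulate_dissociation",
    "simulate_competition",
    "uptake_velocity",
]

#: default sampling times (minutes) of the dissociation assay
DEFAULT_TIMEPOINTS = (5.0, 10.0, 15.0, 20.0, 30.0, 50.0, 70.0)


@dataclass(frozen=True)
class AllostericDissociationModel:
    """Occupancy-gated dissociation-rate model.

    Parameters
    ----------
    k_buffer : float
        Control dissociation rate without modulator (min⁻¹).  The assay is
        run at a temperature where the control half-life is ~15 min, i.e.
        ``k_buffer ≈ ln2/15 ≈ 0.0462`` min⁻¹.
    allo_ic50 : float
        Modulator concentration (nM) halving the dissociation rate.
    hill : float
        Hill coefficient of the occupancy logistic (default 1).
    emax : float
        Fraction of the rate suppressed at saturating modulator, in (0, 1].
    b0 : float
        Specific signal (counts) at t = 0.
    ns_plateau : float
        Nonspecific plateau signal (counts), default 0.
    """

    k_buffer: float
    allo_ic50: float
    hill: float = 1.0
    emax: float = 1.0
    b0: float = 1000.0
    ns_plateau: float = 0.0

    def __post_init__(self) -> None:
        if self.k_buffer <= 0:
            raise ValueError(f"k_buffer must be positive, got {self.k_buffer}")
        if self.allo_ic50 <= 0:
            raise ValueError(f"allo_ic50 must be positive, got {self.allo_ic50}")
        if self.hill <= 0:
            raise ValueError(f"hill must be positive, got {self.hill}")
        if not 0 < self.emax <= 1:
            raise ValueError(f"emax must be in (0, 1], got {self.emax}")
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.ns_plateau < 0:
            raise ValueError(f"ns_plateau must be nonnegative, got {self.ns_plateau}")

    def k_obs(self, c):
        """Observed dissociation rate (min⁻¹) at modulator concentration ``c`` nM."""
        return k_obs(self, c)


def k_obs(model: AllostericDissociationModel, c):
    """Observed S1 dissociation rate under S2 occupancy by ``c`` nM modulator.

    Vectorized over ``c``.  ``k_obs(0) == k_buffer``; the function is
    nonincreasing in ``c``; for ``emax = 1, hill = 1`` it equals
    ``k_buffer/2`` at ``c == allo_ic50``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("modulator concentration must be nonnegative")
    with np.errstate(divide="ignore"):
        # occupancy written on the log scale for numeric symmetry in c
        occ = np.where(
            c > 0,
            1.0 / (1.0 + np.exp(-model.hill * (np.log(np.where(c > 0, c, 1.0)) - math.log(model.allo_ic50)))),
            0.0,
        )
    out = model.k_buffer * (1.0 - model.emax * occ)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class DissociationDesign:
    """Design of a dissociation experiment: sampling times, modulator doses,
    replication and noise level.  Exactly one concentration must be 0 — the
    buffer control defining ``k_buffer``."""

    timepoints: tuple = DEFAULT_TIMEPOINTS
    concentrations: tuple = (0.0,)
    replicates: int = 3
    noise_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.count_nonzero(c == 0) != 1:
            raise ValueError("design must contain exactly one buffer control (c = 0)")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be nonnegative")
        object.__setattr__(self, "timepoints", tuple(t.tolist()))
        object.__setattr__(self, "concentrations", tuple(c.tolist()))


@dataclass
class TimeCourse:
    """One measured or simulated signal-vs-time record."""

    condition: str
    concentration: float
    replicate: int
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.signals < 0):
            raise ValueError("signals must be nonnegative")


def simulate_dissociation(
    model: AllostericDissociationModel, design: DissociationDesign
) -> list[TimeCourse]:
    """Simulate the dissociation assay: one curve per concentration × replicate.

    Signals follow ``ns_plateau + b0·exp(−k_obs(c)·t)`` with multiplicative
    Gaussian noise of relative sd ``design.noise_rel``.  Noise substreams are
    keyed on (seed, condition index, replicate index), so identical seeds give
    byte-identical output.
    """
    t = np.asarray(design.timepoints, dtype=float)
    out: list[TimeCourse] = []
    for ci, c in enumerate(design.concentrations):
        k = k_obs(model, c)
        clean = model.ns_plateau + model.b0 * np.exp(-k * t)
        for rep in range(design.replicates):
            if design.noise_rel > 0:
                rng = np.random.default_rng([design.seed, ci, rep])
                sig = clean * (1.0 + design.noise_rel * rng.standard_normal(t.size))
                sig = np.maximum(sig, 0.0)
            else:
                sig = clean.copy()
            out.append(
                TimeCourse(
                    condition=f"c={c:g}nM",
                    concentration=float(c),
                    replicate=rep,
                    times=t.copy(),
                    signals=sig,
                )
            )
    return out


@dataclass(frozen=True)
class CompetitionModel:
    """One-site competition binding: four-parameter logistic in log-dose."""

    top: float
    bottom: float
    ic50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.bottom < 0:
            raise ValueError("bottom must be nonnegative")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.ic50 <= 0 or self.hill <= 0:
            raise ValueError("ic50 and hill must be positive")

    def response(self, c):
        c = np.asarray(c, dtype=float)
        out = self.bottom + (self.top - self.bottom) / (
            1.0 + (c / self.ic50) ** self.hill
        )
        return out.item() if out.ndim == 0 else out


def simulate_competition(model: CompetitionModel, concs, noise_rel: float = 0.0, seed: int = 0):
    """Simulate a competition binding curve; returns a DoseResponseCurve.

    Responses carry multiplicative Gaussian noise of relative sd ``noise_rel``.
    """
    from .allosteric_potency import DoseResponseCurve  # avoid import cycle

    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(concs < 0):
        raise ValueError("concentrations must be nonnegative")
    resp = model.response(concs)
    resp = np.atleast_1d(np.asarray(resp, dtype=float))
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        resp = resp * (1.0 + noise_rel * rng.standard_normal(resp.size))
    return DoseResponseCurve(concentrations=concs, ratios=resp)


@dataclass(frozen=True)
class MixedInhibitionModel:
    """Michaelis–Menten uptake with mixed inhibition.

    ``ki_c`` is the dissociation constant of the inhibitor for the free
    transporter (competitive component, raises apparent KM); ``ki_u`` the one
    for the transporter–substrate complex (uncompetitive component, lowers
    apparent Vmax).  ``ki_u = inf`` recovers pure competitive inhibition.
    """

    vmax: float
    km: float
    ki_c: float
    ki_u: float = math.inf

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0 or self.ki_c <= 0 or self.ki_u <= 0:
            raise ValueError("all MixedInhibitionModel parameters must be positive")

    def apparent_vmax(self, inhibitor: float) -> float:
        return self.vmax / (1.0 + inhibitor / self.ki_u)

    def apparent_km(self, inhibitor: float) -> float:
        return self.km * (1.0 + inhibitor / self.ki_c) / (1.0 + inhibitor / self.ki_u)


def uptake_velocity(model: MixedInhibitionModel, S, I):
    """Uptake velocity v(S, I) = vmax·S / (km·(1+I/ki_c) + S·(1+I/ki_u))."""
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValueError("substrate and inhibitor concentrations must be nonnegative")
    out = model.vmax * S / (
        model.km * (1.0 + I / model.ki_c) + S * (1.0 + I / model.ki_u)
    )
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class SynergyDesign:
    """Fractional remaining activities under two single agents and their combination."""

    f_a: float
    f_b: float
    f_ab: float

    def __post_init__(self) -> None:
        for name in ("f_a", "f_b", "f_ab"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
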