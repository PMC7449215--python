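"""Deterministic two-compartment IV-infusion kinetics.

Closed-form concentration and AUC for multiple-dose infusion regimens of a
linear two-compartment model parameterised by first-order rate constants:

    dA1/dt = R(t) - (Ke + kcp) * A1 + kpc * A2
    dA2/dt = kcp * A1 - kpc * A2
    C(t)   = A1 / V

with hybrid (macro) constants ``alpha + beta = Ke + kcp + kpc`` and
``alpha * beta = Ke * kpc``.  The unit-bolus impulse response of the central
compartment is ``(A*exp(-alpha*t) + B*exp(-beta*t)) / V``; a constant-rate
infusion is its convolution with a boxcar, and multiple doses superpose.
AUC on any window is the exact integral of the piecewise bi-exponential.

Units are fixed throughout the package: hours, mg, litres, mg/L, mg*h/L.

The central volume carries the study's weight covariate: ``V = V0 * weight /
78`` where 78 kg is the population median weight of the cohort the model
was estimated on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "REFERENCE_WEIGHT_KG",
    "PKParameters",
    "Covariates",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "scaled_volume",
    "concentration_profile",
    "auc_interval",
]

#: Population median body weight (kg) to which V0 is normalised.
REFERENCE_WEIGHT_KG = 78.0

# Relative gap below which the two hybrid rate constants are treated as
# numerically coincident and beta is nudged off alpha.
_DEGENERATE_REL = 1e-9


@dataclass(frozen=True)
class PKParameters:
    """One parameter vector of the two-compartment model.

    Attributes
    ----------
    ke : float
        First-order elimination rate constant from the central compartment
        (1/h).
    v0 : float
        Central volume of distribution normalised to the 78-kg reference
        weight (L).
    kcp : float
        Central-to-peripheral distribution rate constant (1/h).
    kpc : float
        Peripheral-to-central distribution rate constant (1/h).
    """

    ke: float
    v0: float
    kcp: float
    kpc: float

    def __post_init__(self) -> None:
        for name in ("ke", "v0", "kcp", "kpc"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"PKParameters.{name} must be finite and > 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.ke, self.v0, self.kcp, self.kpc])


PARAMETER_NAMES = ("ke", "v0", "kcp", "kpc")


@dataclass(frozen=True)
class Covariates:
    """Subject covariates; total body weight (kg) is mandatory."""

    weight: float
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight is None or not math.isfinite(self.weight) or self.weight <= 0:
            raise ValueError(f"weight must be finite and > 0, got {self.weight!r}")


@dataclass(frozen=True)
class DoseEvent:
    """One IV infusion: `amount` mg infused over `duration` h from `start` h."""

    amount: float
    start: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")
        if self.start < 0:
            raise ValueError(f"dose start must be >= 0, got {self.start}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered IV-infusion dose events with a simulation horizon (h).

    Time origin is the start of the first infusion; dosing windows used in
    the study (0-24, 48-72, ..., 312-336 h) are half-open ``[t0, t1)``.
    """

    events: tuple[DoseEvent, ...]
    horizon: float

    def __init__(self, events: Sequence[DoseEvent], horizon: float | None = None):
        events = tuple(events)
        if any(
            events[i].start > events[i + 1].start for i in range(len(events) - 1)
        ):
            raise ValueError("dose events must be sorted by start time")
        last_end = max((e.end for e in events), default=0.0)
        if horizon is None:
            horizon = last_end
        if horizon < last_end:
            raise ValueError(
                f"horizon {horizon} h precedes last infusion end {last_end} h"
            )
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "horizon", float(horizon))

    @classmethod
    def daily(
        cls,
        loading_mg: float,
        maintenance_mg: float,
        n_days: int,
        duration: float = 1.0,
        interval: float = 24.0,
        horizon: float | None = None,
    ) -> "Regimen":
        """Loading dose at t=0, maintenance every `interval` h thereafter."""
        if n_days < 1:
            raise ValueError("n_days must be >= 1")
        amounts = [loading_mg] + [maintenance_mg] * (n_days - 1)
        events = [
            DoseEvent(amount=a, start=i * interval, duration=duration)
            for i, a in enumerate(amounts)
        ]
        if horizon is None:
            horizon = n_days * interval
        return cls(events, horizon)

    def scaled(self, factor: float) -> "Regimen":
        """Same schedule with every amount multiplied by `factor`."""
        return Regimen(
            [DoseEvent(e.amount * factor, e.start, e.duration) for e in self.events],
            self.horizon,
        )


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment plasma concentrations (mg/L) at sampling times (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.shape != conc.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)


def scaled_volume(params: PKParameters, cov: Covariates) -> float:
    """Central volume for a subject: ``V = V0 * weight / 78`` (L)."""
    if cov.weight is None:
        raise ValueError("weight covariate is mandatory")
    return params.v0 * cov.weight / REFERENCE_WEIGHT_KG


def _hybrid_terms(ke, kcp, kpc):
    """Hybrid constants and bolus coefficients, broadcasting over arrays.

    Returns (alpha, beta, A, B) such that the unit-bolus amount in the
    central compartment is ``A*exp(-alpha t) + B*exp(-beta t)``.  ``beta``
    is computed as ``alpha*beta / alpha`` to avoid cancellation, and nudged
    off ``alpha`` when the two roots coincide to machine level.
    """
    ke = np.asarray(ke, dtype=float)
    kcp = np.asarray(kcp, dtype=float)
    kpc = np.asarray(kpc, dtype=float)
    s = ke + kcp + kpc
    p = ke * kpc
    disc = np.maximum(s * s - 4.0 * p, 0.0)
    alpha = 0.5 * (s + np.sqrt(disc))
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(alpha > 0, p / alpha, 0.0)
    # degenerate repeated root: nudge beta (measure-zero case)
    degenerate = np.abs(alpha - beta) < _DEGENERATE_REL * alpha
    beta = np.where(degenerate, beta * (1.0 - _DEGENERATE_REL), beta)
    gap = alpha - beta
    a_coef = (alpha - kpc) / gap
    b_coef = (kpc - beta) / gap
    return alpha, beta, a_coef, b_coef


def _safe_rate(lam):
    """Replace zero rates by 1 so divisions are defined; callers zero the term."""
    return np.where(lam > 0, lam, 1.0)


def _conc_grid(ke, v, kcp, kpc, events: Sequence[DoseEvent], times) -> np.ndarray:
    """Concentrations for parameter arrays of shape (m,) at times (nt,).

    `v` is the already-weight-scaled central volume.  Returns (m, nt).
    """
    ke = np.atleast_1d(np.asarray(ke, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    kcp = np.atleast_1d(np.asarray(kcp, dtype=float))
    kpc = np.atleast_1d(np.asarray(kpc, dtype=float))
    times = np.asarray(times, dtype=float)
    alpha, beta, a_coef, b_coef = _hybrid_terms(ke, kcp, kpc)
    out = np.zeros((ke.shape[0], times.shape[0]))
    for lam, coef in ((alpha, a_coef), (beta, b_coef)):
        lam_c = _safe_rate(lam)[:, None]
        coef_c = (np.where(lam > 0, coef, 0.0) / v)[:, None]
        for ev in events:
            if ev.amount == 0.0:
                continue
            u = times[None, :] - ev.start
            during = coef_c * ev.rate / lam_c * (
                1.0 - np.exp(-lam_c * np.clip(u, 0.0, ev.duration))
            )
            decay = np.exp(-lam_c * np.maximum(u - ev.duration, 0.0))
            out += np.where(u > 0, during * decay, 0.0)
    return out


def _auc_grid(ke, v, kcp, kpc, events: Sequence[DoseEvent], t0: float, t1: float) -> np.ndarray:
    """Exact AUC over [t0, t1] for parameter arrays of shape (m,).

    Sums, per dose event and per exponential term, the analytic primitive of
    the infusion-phase ramp and the post-infusion decay.
    """
    ke = np.atleast_1d(np.asarray(ke, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    kcp = np.atleast_1d(np.asarray(kcp, dtype=float))
    kpc = np.atleast_1d(np.asarray(kpc, dtype=float))
    if t1 <= t0:
        raise ValueError(f"AUC window must satisfy t0 < t1, got [{t0}, {t1}]")
    alpha, beta, a_coef, b_coef = _hybrid_terms(ke, kcp, kpc)
    out = np.zeros(ke.shape[0])
    for lam, coef in ((alpha, a_coef), (beta, b_coef)):
        lam_c = _safe_rate(lam)
        coef_c = np.where(lam > 0, coef, 0.0) / v
        for ev in events:
            if ev.amount == 0.0:
                continue
            a = max(t0 - ev.start, 0.0)
            b = t1 - ev.start
            if b <= 0:
                continue
            scale = coef_c * ev.rate / lam_c
            # infusion phase: integral of (1 - exp(-lam u)) du on [a, min(b, T)]
            lo, hi = min(a, ev.duration), min(b, ev.duration)
            if hi > lo:
                out += scale * (
                    (hi - lo) + (np.exp(-lam_c * hi) - np.exp(-lam_c * lo)) / lam_c
                )
            # post-infusion phase: (1 - exp(-lam T)) exp(-lam (u - T)) on [max(a,T), b]
            lo2, hi2 = max(a, ev.duration), b
            if hi2 > lo2:
                out += (
                    scale
                    * (1.0 - np.exp(-lam_c * ev.duration))
                    / lam_c
                    * (
                        np.exp(-lam_c * (lo2 - ev.duration))
                        - np.exp(-lam_c * (hi2 - ev.duration))
                    )
                )
    return out


def concentration_profile(
    params: PKParameters,
    cov: Covariates,
    regimen: Regimen,
    times: Sequence[float],
) -> ConcentrationProfile:
    """Predict central concentrations at the requested times.

    Times must lie within ``[0, horizon]``.  The closed-form bi-exponential
    solution with superposition over dose events is exact for this linear
    model; concentrations are analytically non-negative.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > regimen.horizon):
        raise ValueError(
            f"times must lie within [0, {regimen.horizon}] h"
        )
    v = scaled_volume(params, cov)
    conc = _conc_grid(params.ke, v, params.kcp, params.kpc, regimen.events, times)[0]
    return ConcentrationProfile(times=times, concentrations=conc)


def auc_interval(
    params: PKParameters,
    cov: Covariates,
    regimen: Regimen,
    t0: float,
    t1: float,
) -> float:
    """Exact AUC (mg*h/L) of the model concentration over ``[t0, t1]``."""
    if not (0 <= t0 < t1 <= regimen.horizon):
        raise ValueError(
            f"window [{t0}, {t1}] must satisfy 0 <= t0 < t1 <= horizon={regimen.horizon}"
        )
    v = scaled_volume(params, cov)
    return float(
        _auc_grid(params.ke, v, params.kcp, params.kpc, regimen.events, t0, t1)[0]
    )
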