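"""Closed-form structural pharmacokinetic models for repeated oral dosing.

All functions work in the unit system of the study they support: dose amounts
in mg, volumes in L, clearances in L/h, rate constants in 1/h, times in hours
since the first administration, and concentrations in ng/mL (amounts in mg
over volumes in L give mg/L = µg/mL, multiplied by 1000 on output).

The disposition models are linear, so multiple dosing is handled by
superposition of single-dose solutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "DoseEvent",
    "ConcentrationProfile",
    "conc_one_cpt_oral",
    "conc_two_cpt_oral",
    "conc_zero_order_oral",
    "exposure_metrics",
    "MG_PER_L_TO_NG_PER_ML",
]

#: mg/L (= µg/mL) to ng/mL
MG_PER_L_TO_NG_PER_ML = 1000.0

#: relative |ka - ke| threshold below which the ka -> ke analytic limit is used
KA_KE_DEGENERACY_RTOL = 1e-8


class InvalidParameterError(ValueError):
    """A pharmacokinetic parameter violates its positivity/consistency rules."""


class InputError(ValueError):
    """Malformed dosing or observation input."""


@dataclass(frozen=True)
class PKParameters:
    """Apparent (oral) pharmacokinetic parameters of one subject.

    Parameters
    ----------
    cl_f : float
        Apparent clearance CL/F, L/h.
    v_f : float
        Apparent central volume V/F, L.
    ka : float, optional
        First-order absorption rate constant, 1/h. Mutually exclusive with
        ``d0``.
    d0 : float, optional
        Zero-order absorption duration, h. Mutually exclusive with ``ka``.
    q : float, optional
        Intercompartmental clearance, L/h (two-compartment extension).
    v2_f : float, optional
        Apparent peripheral volume, L (required when ``q`` is set).
    """

    cl_f: float
    v_f: float
    ka: float | None = None
    d0: float | None = None
    q: float | None = None
    v2_f: float | None = None

    def __post_init__(self) -> None:
        if not (self.cl_f > 0 and self.v_f > 0):
            raise InvalidParameterError(
                f"cl_f and v_f must be strictly positive (got {self.cl_f}, {self.v_f})"
            )
        if (self.ka is None) == (self.d0 is None):
            raise InvalidParameterError(
                "exactly one absorption mode must be set (ka or d0)"
            )
        if self.ka is not None and not self.ka > 0:
            raise InvalidParameterError(f"ka must be strictly positive (got {self.ka})")
        if self.d0 is not None and not self.d0 >= 0:
            raise InvalidParameterError(f"d0 must be non-negative (got {self.d0})")
        if (self.q is None) != (self.v2_f is None):
            raise InvalidParameterError("q and v2_f must be set together")
        if self.q is not None:
            if self.q < 0 or not self.v2_f > 0:
                raise InvalidParameterError(
                    f"q must be >= 0 and v2_f > 0 (got {self.q}, {self.v2_f})"
                )

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/F ÷ V/F, 1/h."""
        return self.cl_f / self.v_f


@dataclass(frozen=True)
class DoseEvent:
    """A single oral administration: ``time`` hours after the study origin, ``amount`` mg."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InputError(f"dose time must be >= 0 (got {self.time})")
        if not self.amount > 0:
            raise InputError(f"dose amount must be > 0 (got {self.amount})")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentrations (ng/mL) evaluated on a time grid (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        if self.times.shape != self.concentrations.shape:
            raise InputError("times and concentrations must have the same shape")


def _dose_arrays(doses: Sequence[DoseEvent]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([d.time for d in doses], dtype=float)
    amounts = np.array([d.amount for d in doses], dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise InputError("dose events must be sorted by time")
    return times, amounts


def one_cpt_first_order_conc(
    t: np.ndarray,
    dose_times: np.ndarray,
    dose_amounts: np.ndarray,
    cl: float | np.ndarray,
    v: float,
    ka: float,
) -> np.ndarray:
    """Vectorised one-compartment first-order absorption superposition.

    ``cl`` may be a scalar or an array broadcastable against ``t`` (used for
    occasion-varying covariate effects on clearance). Returns ng/mL.
    """
    t = np.asarray(t, dtype=float)
    if dose_times.size == 0:
        return np.zeros_like(t)
    ke = np.asarray(cl, dtype=float) / v  # scalar or (nt,)
    dt = t[None, :] - dose_times[:, None]  # (ndose, nt)
    active = dt > 0
    dtp = np.where(active, dt, 0.0)
    ke_b = np.broadcast_to(np.atleast_1d(ke), t.shape)[None, :]
    degen = np.abs(ka - ke_b) < KA_KE_DEGENERACY_RTOL * ka
    # regular branch; guard the degenerate denominator
    denom = np.where(degen, 1.0, ka - ke_b)
    reg = ka / (v * denom) * (np.exp(-ke_b * dtp) - np.exp(-ka * dtp))
    lim = ka * dtp * np.exp(-ka * dtp) / v
    per_dose = np.where(degen, lim, reg) * dose_amounts[:, None]
    conc = np.where(active, per_dose, 0.0).sum(axis=0)
    return conc * MG_PER_L_TO_NG_PER_ML


def conc_one_cpt_oral(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
) -> ConcentrationProfile:
    """One-compartment disposition, first-order absorption and elimination.

    Superposition over all administrations of
    ``D·ka / (V·(ka−ke)) · (exp(−ke·Δt) − exp(−ka·Δt))`` for Δt ≥ 0, with the
    analytic limit ``D·ka·Δt·exp(−ka·Δt)/V`` when ka ≈ ke.
    """
    if params.ka is None:
        raise InvalidParameterError("conc_one_cpt_oral requires first-order absorption (ka)")
    t = np.asarray(times, dtype=float)
    dose_times, dose_amounts = _dose_arrays(doses)
    conc = one_cpt_first_order_conc(
        t, dose_times, dose_amounts, params.cl_f, params.v_f, params.ka
    )
    return ConcentrationProfile(t, conc)


def conc_two_cpt_oral(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
) -> ConcentrationProfile:
    """Two-compartment disposition with first-order absorption.

    Standard macro-constant (A, B, C) tri-exponential solution, superposed
    over doses. Reduces to the one-compartment solution as q → 0.
    """
    if params.ka is None:
        raise InvalidParameterError("conc_two_cpt_oral requires first-order absorption (ka)")
    if params.q is None:
        raise InvalidParameterError("conc_two_cpt_oral requires q and v2_f")
    t = np.asarray(times, dtype=float)
    dose_times, dose_amounts = _dose_arrays(doses)
    if dose_times.size == 0:
        return ConcentrationProfile(t, np.zeros_like(t))
    ka = params.ka
    ke = params.cl_f / params.v_f
    k12 = params.q / params.v_f
    k21 = params.q / params.v2_f
    s = ke + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * ke * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    # guard exact coincidences by tiny perturbation (measure-zero configurations)
    eps = 1e-12 * max(alpha, ka, 1.0)
    if abs(alpha - beta) < eps:
        alpha += eps
    if abs(ka - alpha) < eps:
        alpha += eps
    if abs(ka - beta) < eps:
        beta -= eps
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    cc = (k21 - ka) / ((alpha - ka) * (beta - ka))
    dt = t[None, :] - dose_times[:, None]
    active = dt > 0
    dtp = np.where(active, dt, 0.0)
    tri = (
        ca * np.exp(-alpha * dtp)
        + cb * np.exp(-beta * dtp)
        + cc * np.exp(-ka * dtp)
    )
    per_dose = dose_amounts[:, None] * ka / params.v_f * tri
    conc = np.where(active, per_dose, 0.0).sum(axis=0)
    return ConcentrationProfile(t, conc * MG_PER_L_TO_NG_PER_ML)


def conc_zero_order_oral(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
) -> ConcentrationProfile:
    """One-compartment disposition with zero-order (constant-rate) absorption.

    Each dose enters the central compartment at rate D/d0 for d0 hours.
    Closed form in the infusion phase, ``(R/CL)(1−exp(−ke τ))``, and the
    post-infusion washout. The d0 → 0 limit is the oral bolus D/V·exp(−ke·t).
    """
    if params.d0 is None:
        raise InvalidParameterError("conc_zero_order_oral requires a zero-order duration (d0)")
    t = np.asarray(times, dtype=float)
    dose_times, dose_amounts = _dose_arrays(doses)
    if dose_times.size == 0:
        return ConcentrationProfile(t, np.zeros_like(t))
    ke = params.ke
    dt = t[None, :] - dose_times[:, None]
    active = dt > 0
    dtp = np.where(active, dt, 0.0)
    if params.d0 <= 0:
        per_dose = dose_amounts[:, None] / params.v_f * np.exp(-ke * dtp)
    else:
        rate = dose_amounts[:, None] / params.d0  # mg/h
        during = rate / params.cl_f * (1.0 - np.exp(-ke * np.minimum(dtp, params.d0)))
        post = (
            rate
            / params.cl_f
            * (1.0 - np.exp(-ke * params.d0))
            * np.exp(-ke * np.maximum(dtp - params.d0, 0.0))
        )
        per_dose = np.where(dtp <= params.d0, during, post)
    conc = np.where(active, per_dose, 0.0).sum(axis=0)
    return ConcentrationProfile(t, conc * MG_PER_L_TO_NG_PER_ML)


def exposure_metrics(
    profile: ConcentrationProfile,
    interval: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Trough, peak and time of peak over a dosing interval.

    The profile is expected on a dense grid covering the interval; extrema are
    taken over grid points (dense-grid search, so the same code handles
    irregular multi-dose intervals).

    Returns ``{"cmin", "cmax", "tmax"}`` with concentrations in ng/mL and
    ``tmax`` in hours.
    """
    t = profile.times
    c = profile.concentrations
    if interval is not None:
        lo, hi = interval
        sel = (t >= lo) & (t <= hi)
        if not sel.any():
            raise InputError("interval contains no grid points")
        t, c = t[sel], c[sel]
    imax = int(np.argmax(c))
    return {"cmin": float(c.min()), "cmax": float(c[imax]), "tmax": float(t[imax])}
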