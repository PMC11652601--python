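"""Closed-form one-compartment, first-order-absorption oral pharmacokinetics.

The structural model is the classic one-compartment disposition with
first-order absorption from a depot (gut) compartment, parameterized by
apparent oral clearance CL/F (L/h), apparent volume V/F (L) and the
absorption rate constant ka (1/h).  Single doses, finite multiple-dose
trains and the analytic steady-state (n -> infinity) limit are all
supported through the standard accumulation factors.

Unit contract: dose in mg, volume in L, time in h, concentration in ng/mL.
The single mg/L -> ng/mL factor of 1000 is applied in exactly one place
(:data:`MG_PER_L_TO_NG_PER_ML` inside :func:`_conc_kernel`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructuralParams",
    "DoseRegimen",
    "ConcentrationProfile",
    "concentration",
    "steady_state_trough",
    "InvalidRegimenError",
]

#: conversion factor, 1 mg/L = 1000 ng/mL; applied in _conc_kernel only
MG_PER_L_TO_NG_PER_ML = 1000.0

#: relative |ka - ke| threshold below which the analytic ka -> ke limit is used
_KA_KE_TOL = 1e-8


class InvalidRegimenError(ValueError):
    """Raised for dosing regimens that violate their invariants."""


@dataclass(frozen=True)
class StructuralParams:
    """Structural PK parameters of one individual.

    Attributes
    ----------
    cl : float
        Apparent oral clearance CL/F, L/h.  Strictly positive.
    v : float
        Apparent volume of distribution V/F, L.  Strictly positive.
    ka : float
        First-order absorption rate constant, 1/h.  Strictly positive.
    """

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0 and self.ka > 0):
            raise ValueError(
                f"StructuralParams must be strictly positive, got "
                f"cl={self.cl}, v={self.v}, ka={self.ka}"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseRegimen:
    """An oral dosing regimen: repeated administrations of equal amount.

    ``n_doses=None`` marks the steady-state (n -> infinity) limit.
    For a single dose use ``n_doses=1``; ``interval`` is then ignored.
    """

    dose_amount: float  # mg per administration
    interval: float | None = None  # tau, h
    n_doses: int | None = 1  # None => steady state

    def __post_init__(self) -> None:
        if self.dose_amount < 0:
            raise InvalidRegimenError(f"dose_amount must be >= 0, got {self.dose_amount}")
        repeated = self.n_doses is None or self.n_doses > 1
        if repeated and (self.interval is None or self.interval <= 0):
            raise InvalidRegimenError(
                "repeated dosing requires a strictly positive interval, got "
                f"interval={self.interval}"
            )
        if self.n_doses is not None and self.n_doses < 1:
            raise InvalidRegimenError(f"n_doses must be >= 1 or None, got {self.n_doses}")

    @property
    def steady_state(self) -> bool:
        return self.n_doses is None


@dataclass(frozen=True)
class ConcentrationProfile:
    """Times (h since first dose) paired with concentrations (ng/mL)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have the same shape")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def _accumulation(x: np.ndarray, tau: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Accumulation factor A_x = (1 - e^(-n x tau)) / (1 - e^(-x tau)).

    ``n = inf`` gives the steady-state limit 1 / (1 - e^(-x tau));
    ``tau = inf`` (single dose) gives 1.
    """
    xt = x * tau
    with np.errstate(over="ignore", invalid="ignore"):
        denom = -np.expm1(-xt)
        num = np.where(np.isinf(n), 1.0, -np.expm1(-n * xt))
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 1.0)
    # single dose (tau -> inf): denom -> 1, num -> 1, handled naturally,
    # but xt may be inf*0 = nan for x == 0 paths; x > 0 always here.
    return np.where(np.isinf(tau), 1.0, out)


def _acc_derivative(x: np.ndarray, tau: np.ndarray, n: np.ndarray) -> np.ndarray:
    """d/dx of the accumulation factor, used by the ka -> ke limit branch."""
    xt = x * tau
    with np.errstate(over="ignore", invalid="ignore"):
        e = np.exp(-xt)
        denom = -np.expm1(-xt)
        ss = -tau * e / denom**2  # steady-state branch
        en = np.exp(-n * xt)
        fin = (n * tau * en * denom - (-np.expm1(-n * xt)) * tau * e) / denom**2
        out = np.where(np.isinf(n), ss, fin)
    return np.where(np.isinf(tau), 0.0, out)


def _conc_kernel(cl, v, ka, amount, tad, tau, n):
    """Vectorized concentration kernel, ng/mL.  All arguments broadcast.

    ``tad`` is time after the most recent dose of the train, ``tau`` the
    interval (``inf`` for a single dose), ``n`` the number of doses given
    so far (``inf`` for steady state).  The ka == ke degeneracy is handled
    by the analytic limit, not a crash.
    """
    cl, v, ka, amount, tad, tau, n = np.broadcast_arrays(
        *map(np.asarray, (cl, v, ka, amount, tad, tau, n))
    )
    ke = cl / v
    diff = ka - ke
    degenerate = np.abs(diff) < _KA_KE_TOL * ka
    safe_diff = np.where(degenerate, 1.0, diff)

    a_e = _accumulation(ke, tau, n)
    a_a = _accumulation(ka, tau, n)
    general = (
        amount * ka / (v * safe_diff) * (a_e * np.exp(-ke * tad) - a_a * np.exp(-ka * tad))
    )

    if np.any(degenerate):
        # limit ka -> ke of A(ke) e^(-ke t) - A(ka) e^(-ka t) over (ka - ke)
        # equals -d/dx [A(x) e^(-x t)] at x = ke
        f_prime = np.exp(-ke * tad) * (_acc_derivative(ke, tau, n) - tad * a_e)
        limit = -amount * ka / v * f_prime
        general = np.where(degenerate, limit, general)

    return np.maximum(general, 0.0) * MG_PER_L_TO_NG_PER_ML


def concentration(params: StructuralParams, regimen: DoseRegimen, t) -> float | np.ndarray:
    """Concentration (ng/mL) at time ``t`` (h) after the most recent dose.

    For a multiple-dose train the accumulation factors
    ``A_x = (1 - e^(-n x tau)) / (1 - e^(-x tau))`` account for the n
    doses already given; at steady state the ``1/(1 - e^(-x tau))`` limit
    is used.  ``t`` may be a scalar or array; for steady-state regimens
    ``t`` beyond one interval wraps periodically (dosing continues).

    Raises
    ------
    ValueError
        If ``t`` is negative.
    InvalidRegimenError
        Via :class:`DoseRegimen` construction.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since last dose must be non-negative")
    if regimen.steady_state:
        tau = regimen.interval
        tad = np.mod(t, tau)
        # t exactly on a dosing time means the pre-dose trough of the
        # periodic profile; the kernel is periodic so tad=0 equals tad=tau
        n = np.inf
    elif regimen.n_doses == 1:
        tau, tad, n = np.inf, t, 1.0
    else:
        tau, tad, n = regimen.interval, t, float(regimen.n_doses)
    out = _conc_kernel(params.cl, params.v, params.ka, regimen.dose_amount, tad, tau, n)
    return float(out) if out.ndim == 0 else out


def steady_state_trough(params: StructuralParams, regimen: DoseRegimen) -> float:
    """Steady-state trough: concentration at ``t = interval`` in the n -> inf limit.

    The regimen must be marked steady state (``n_doses=None``).
    """
    if not regimen.steady_state:
        raise InvalidRegimenError("steady_state_trough requires a steady-state regimen")
    return float(
        _conc_kernel(
            params.cl,
            params.v,
            params.ka,
            regimen.dose_amount,
            regimen.interval,
            regimen.interval,
            np.inf,
        )
    )
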