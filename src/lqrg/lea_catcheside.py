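"""Generalized Lea-Catcheside dose-protraction factor.

The two-track (quadratic) cell-killing term of linear-quadratic models is
attenuated by the dose-protraction factor

    G(tau) = (2 / D^2) * int_0^T R(u) du  int_0^u R(w) exp(-(u - w)/tau) dw,

where R is the dose-rate function of the schedule and tau the first-order
recovery time constant (DNA repair time tau_R, or resensitization time tau_S).
G lies in (0, 1]: 1 for a single acute exposure, 1/n for n well-separated
acute fractions (complete inter-fraction recovery), and in between when
fractions interact through incomplete recovery.

For schedules made of instantaneous fractions the double integral collapses
to an exact pairwise-exponential sum, which is what this module uses; the
singular delta-function limit makes quadrature inappropriate there. For
finite fraction durations the outer integral is evaluated by adaptive
quadrature over a closed-form inner integral (piecewise-constant dose rate).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import integrate

from .schedule import FractionationSchedule

__all__ = ["lea_catcheside_G", "G_equal_acute_fractions", "G_continuous"]


@lru_cache(maxsize=256)
def _pairwise_dt_matrix(schedule: FractionationSchedule):
    """|t_i - t_j| matrix and dose vector, cached per schedule."""
    t = schedule.start_times_array()
    d = schedule.doses_array()
    return np.abs(t[:, None] - t[None, :]), d


def _G_instantaneous(schedule: FractionationSchedule, tau: float) -> float:
    dt, d = _pairwise_dt_matrix(schedule)
    total = float(d @ np.exp(-dt / tau) @ d)
    return total / schedule.total_dose_gy ** 2


def _inner_integral(u: float, pulses, tau: float) -> float:
    """int_0^u R(w) exp(-(u-w)/tau) dw for piecewise-constant/delta R."""
    acc = 0.0
    for a, dur, dose in pulses:
        if a >= u:
            break
        if dur == 0.0:
            acc += dose * math.exp(-(u - a) / tau)
        else:
            hi = min(a + dur, u)
            rate = dose / dur
            acc += rate * tau * (math.exp(-(u - hi) / tau) - math.exp(-(u - a) / tau))
    return acc


def _G_quadrature(schedule: FractionationSchedule, tau: float) -> float:
    """Adaptive quadrature of the outer integral; abs tolerance 1e-8 on G."""
    pulses = list(zip(schedule.start_times_h, schedule.durations_h, schedule.doses_gy))
    D = schedule.total_dose_gy
    # absolute tolerance on G maps to tol * D^2 / 2 on the raw double integral,
    # split across the outer pulses
    epsabs = 1e-8 * D * D / (2.0 * len(pulses))
    total = 0.0
    for a, dur, dose in pulses:
        if dur == 0.0:
            # delta pulse: outer integral contributes dose * inner(a) plus the
            # same-instant self term dose^2 / 2
            total += dose * _inner_integral(a, pulses, tau) + 0.5 * dose * dose
        else:
            rate = dose / dur
            val, _ = integrate.quad(
                lambda u: rate * _inner_integral(u, pulses, tau),
                a, a + dur, epsabs=epsabs, limit=200,
            )
            total += val
    return 2.0 * total / (D * D)


def lea_catcheside_G(schedule: FractionationSchedule, tau: float) -> float:
    """Generalized Lea-Catcheside factor G(tau) for an arbitrary schedule.

    Parameters
    ----------
    schedule
        Fractionation schedule defining the dose-rate function R(u).
    tau
        Recovery time constant in hours; must be > 0.

    Returns
    -------
    float
        G in (0, 1].
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if schedule.is_instantaneous:
        g = _G_instantaneous(schedule, tau)
    else:
        g = _G_quadrature(schedule, tau)
    # guard against tiny numerical overshoot at the tau -> inf end
    return min(g, 1.0)


def G_equal_acute_fractions(n: int, interval_h: float, tau: float) -> float:
    """Closed-form G for n equal instantaneous fractions at a fixed interval.

    Standard incomplete-repair result: with phi = exp(-interval/tau),

        G = 1/n + (2/n^2) * phi/(1-phi) * (n - (1-phi^n)/(1-phi)).

    Limits: phi -> 0 gives 1/n (complete inter-fraction recovery);
    phi -> 1 gives 1 (no recovery, single-exposure equivalent).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if interval_h <= 0:
        raise ValueError("interval must be > 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if n == 1:
        return 1.0
    x = interval_h / tau
    if x < 1e-9:  # phi -> 1: no recovery between fractions
        return 1.0
    phi = math.exp(-x)
    one_minus_phi = -math.expm1(-x)
    geom = -math.expm1(-n * x) / one_minus_phi  # (1 - phi^n)/(1 - phi)
    g = 1.0 / n + (2.0 / n ** 2) * (phi / one_minus_phi) * (n - geom)
    return min(g, 1.0)


def G_continuous(duration_h: float, tau: float) -> float:
    """Closed-form G for a single constant-rate exposure of given duration.

    G = (2 tau / T) * [1 - (tau / T) * (1 - exp(-T/tau))].
    """
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if duration_h == 0.0:
        return 1.0
    r = tau / duration_h
    return min(2.0 * r * (1.0 + r * math.expm1(-1.0 / r)), 1.0)
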