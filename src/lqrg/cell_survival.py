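"""Clonogen surviving fraction, BED and effective beta.

Two cell-survival models are implemented.

**LQRG** extends the linear-quadratic model with the four "R"s of
radiobiology and Gompertzian post-treatment growth. The log surviving
fraction at time t after the end of a course delivering total dose D over
treatment time T is

    ln SF(t) = -alpha*D - beta*G(tau_R)*D^2 + (sigma^2/2)*G(tau_S)*D^2
               + ln2 * max(0, T - T_k)/tau_P + (ln2 * t/tau_P)^delta

where G is the Lea-Catcheside dose-protraction factor, tau_R the repair
time, tau_S the resensitization (redistribution + reoxygenation) time,
sigma^2 the variance of the radiosensitivity distribution, tau_P the
clonogen doubling time, T_k the lag before in-treatment repopulation
starts, and delta the Gompertz exponent of post-treatment regrowth.

**Classical LQ** keeps only the first-order and fully-repaired quadratic
killing (G = 1/n, i.e. -beta*D*d for uniform fraction size d) plus
exponential repopulation in and after treatment:

    ln SF(t) = -alpha*D - beta*D*d + ln2 * max(0, T - T_k)/tau_P
               + ln2 * t/tau_P.

The repopulation term is clamped at T = T_k: no "negative regrowth" is
credited for courses shorter than the lag time.

Time bookkeeping: schedules are in hours; the repopulation and Gompertz
terms are evaluated in days (tau_P is a doubling time in days).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from ._units import HOURS_PER_DAY
from .lea_catcheside import lea_catcheside_G
from .schedule import FractionationSchedule

__all__ = [
    "LQRGParams",
    "LQParams",
    "surviving_fraction_lqrg",
    "surviving_fraction_lq",
    "log_sf_lqrg",
    "log_sf_lq",
    "bed_lqrg",
    "beta_eff",
    "BetaEffResult",
]

log = logging.getLogger(__name__)

LN2 = math.log(2.0)

# JSON field names follow the conventional symbols for these parameters.
_LQRG_JSON_KEYS = {
    "rho_per_cm3": "rho",
    "alpha": "alpha",
    "beta": "beta",
    "sigma2": "sigma2",
    "tau_r_h": "tau_R",
    "tau_s_h": "tau_S",
    "tau_p_days": "tau_P",
    "t_k_h": "T_k",
    "k_cr": "K_cr",
    "sigma_k": "sigma_k",
    "delta": "delta",
}
_LQ_JSON_KEYS = {
    "rho_per_cm3": "rho",
    "alpha": "alpha",
    "beta": "beta",
    "tau_p_days": "tau_P",
    "t_k_h": "T_k",
}


def _require_positive(obj, names):
    for name in names:
        if getattr(obj, name) <= 0:
            raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class LQRGParams:
    """LQRG model parameters; defaults are the packaged NSCLC cohort fit.

    Units: alpha Gy^-1, beta and sigma2 Gy^-2, tau_R/tau_S/T_k hours,
    tau_P days, rho clonogens per cm^3, K_cr and sigma_k clonogen counts,
    delta dimensionless in (0, 1].
    """

    alpha: float = 0.06691
    beta: float = 0.1039
    sigma2: float = 0.1939
    tau_r_h: float = 6.32
    tau_s_h: float = 3.04
    tau_p_days: float = 84.55
    t_k_h: float = 533.5
    delta: float = 0.2645
    rho_per_cm3: float = 2.296e9
    k_cr: float = 2.367e9
    sigma_k: float = 1.03e9

    def __post_init__(self):
        _require_positive(self, [f.name for f in self.__dataclass_fields__.values()])
        if self.delta > 1.0:
            raise ValueError("delta must lie in (0, 1]")

    def replace(self, **kwargs) -> "LQRGParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {json_key: getattr(self, attr) for attr, json_key in _LQRG_JSON_KEYS.items()}

    @classmethod
    def from_dict(cls, data: dict) -> "LQRGParams":
        inv = {v: k for k, v in _LQRG_JSON_KEYS.items()}
        return cls(**{inv[k]: v for k, v in data.items()})


@dataclass(frozen=True)
class LQParams:
    """Classical LQ model parameters; defaults are the packaged cohort fit."""

    alpha: float = 0.3932
    beta: float = 0.0429
    tau_p_days: float = 113.8
    t_k_h: float = 246.06
    rho_per_cm3: float = 7.965e9

    def __post_init__(self):
        _require_positive(self, [f.name for f in self.__dataclass_fields__.values()])

    def replace(self, **kwargs) -> "LQParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {json_key: getattr(self, attr) for attr, json_key in _LQ_JSON_KEYS.items()}

    @classmethod
    def from_dict(cls, data: dict) -> "LQParams":
        inv = {v: k for k, v in _LQ_JSON_KEYS.items()}
        return cls(**{inv[k]: v for k, v in data.items()})


def _check_elapsed(t_hours):
    t = np.asarray(t_hours, dtype=float)
    if np.any(t < 0):
        raise ValueError("elapsed time since end of treatment must be >= 0")
    return t


def _regrowth_days(schedule: FractionationSchedule, t_k_h: float) -> float:
    """max(0, T - T_k) in days."""
    return max(0.0, schedule.overall_time_h - t_k_h) / HOURS_PER_DAY


def log_sf_lqrg(params: LQRGParams, schedule: FractionationSchedule, t_hours):
    """ln SF(t) under the LQRG model; vectorized over t (hours post-treatment)."""
    t = _check_elapsed(t_hours)
    D = schedule.total_dose_gy
    g_r = lea_catcheside_G(schedule, params.tau_r_h)
    g_s = lea_catcheside_G(schedule, params.tau_s_h)
    t_days = t / HOURS_PER_DAY
    exponent = (
        -params.alpha * D
        - params.beta * g_r * D * D
        + 0.5 * params.sigma2 * g_s * D * D
        + LN2 * _regrowth_days(schedule, params.t_k_h) / params.tau_p_days
        + np.power(LN2 * t_days / params.tau_p_days, params.delta)
    )
    return exponent if exponent.shape else float(exponent)


def surviving_fraction_lqrg(params: LQRGParams, schedule: FractionationSchedule, t_hours):
    """Surviving fraction SF(t) under the LQRG model."""
    # cap the exponent: regrowth can push SF far above float range during
    # parameter searches, where only "astronomically large" matters
    return np.exp(np.minimum(log_sf_lqrg(params, schedule, t_hours), 700.0))


def log_sf_lq(params: LQParams, schedule: FractionationSchedule, t_hours):
    """ln SF(t) under the classical LQ model with complete inter-fraction repair.

    The quadratic term uses G = sum(d_i^2)/D^2, which equals 1/n (i.e.
    -beta*D*d) for uniform fraction sizes; non-uniform schedules are accepted
    with a logged notice.
    """
    t = _check_elapsed(t_hours)
    D = schedule.total_dose_gy
    d = schedule.doses_array()
    if not schedule.is_uniform:
        log.info("non-uniform fraction sizes: classical-LQ quadratic term uses G = sum(d_i^2)/D^2")
    g = float(np.sum(d * d)) / (D * D)
    t_days = t / HOURS_PER_DAY
    exponent = (
        -params.alpha * D
        - params.beta * g * D * D
        + LN2 * _regrowth_days(schedule, params.t_k_h) / params.tau_p_days
        + LN2 * t_days / params.tau_p_days
    )
    return exponent if exponent.shape else float(exponent)


def surviving_fraction_lq(params: LQParams, schedule: FractionationSchedule, t_hours):
    """Surviving fraction SF(t) under the classical LQ model."""
    return np.exp(np.minimum(log_sf_lq(params, schedule, t_hours), 700.0))


def bed_lqrg(params: LQRGParams, schedule: FractionationSchedule) -> float:
    """Biologically effective dose (Gy) under the LQRG model.

    BED = D + beta*G(tau_R)*D^2/alpha - (sigma^2/2)*G(tau_S)*D^2/alpha
            - ln2 * max(0, T - T_k) / (alpha * tau_P),

    i.e. -ln SF(0) / alpha; resensitization and in-treatment repopulation
    reduce the effective dose, incomplete repair increases it.
    """
    D = schedule.total_dose_gy
    g_r = lea_catcheside_G(schedule, params.tau_r_h)
    g_s = lea_catcheside_G(schedule, params.tau_s_h)
    return (
        D
        + params.beta * g_r * D * D / params.alpha
        - 0.5 * params.sigma2 * g_s * D * D / params.alpha
        - LN2 * _regrowth_days(schedule, params.t_k_h) / (params.alpha * params.tau_p_days)
    )


@dataclass(frozen=True)
class BetaEffResult:
    """Effective quadratic coefficient and the alpha/beta_eff ratio.

    ``alpha_over_beta_eff`` is None when beta_eff <= 0 (ratio undefined);
    this is flagged rather than raised so parameter scans stay usable.
    """

    beta_eff: float
    alpha_over_beta_eff: float | None

    @property
    def defined(self) -> bool:
        return self.alpha_over_beta_eff is not None


def beta_eff(params: LQRGParams, schedule: FractionationSchedule) -> BetaEffResult:
    """Recast the LQRG quadratic terms as an effective LQ beta.

    For n uniform fractions of size d,

        beta_eff = n*beta*G(tau_R) - (n/2)*sigma^2*G(tau_S)

    makes -beta_eff*D*d equal the combined quadratic terms of the LQRG
    exponent, so alpha/beta_eff is comparable with the classical alpha/beta.
    """
    if not schedule.is_uniform:
        raise ValueError("beta_eff is defined for uniform fraction sizes only")
    n = schedule.n_fractions
    g_r = lea_catcheside_G(schedule, params.tau_r_h)
    g_s = lea_catcheside_G(schedule, params.tau_s_h)
    be = n * params.beta * g_r - 0.5 * n * params.sigma2 * g_s
    ratio = params.alpha / be if be > 0 else None
    return BetaEffResult(beta_eff=be, alpha_over_beta_eff=ratio)
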