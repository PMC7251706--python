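"""Tumor control probability from surviving fraction and clonogen statistics.

The number of clonogens left after treatment is K(t) = K_0 * SF(t) with
K_0 = rho * V the initial clonogen count. Two TCP links are provided:

* Gaussian (used with LQRG): the tumor is controlled while K stays below a
  critical number K_cr whose population spread is sigma_k, giving
  TCP = 1 - Phi((K_0*SF - K_cr)/sigma_k).
* Poisson/binomial (used with classical LQ): control requires zero surviving
  clonogens, TCP = exp(-K_0*SF) (or exactly (1-SF)^K_0).

Because SF grows with time after treatment (repopulation), TCP(t) is a
non-increasing curve that plays the role of a model-implied loco-regional
progression-free survival function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from ._units import months_to_hours
from .cell_survival import (
    LQParams,
    LQRGParams,
    surviving_fraction_lq,
    surviving_fraction_lqrg,
)
from .schedule import FractionationSchedule

__all__ = ["TumorSpec", "tcp_gaussian", "tcp_poisson", "tcp_time_curve"]


@dataclass(frozen=True)
class TumorSpec:
    """A tumor known by its gross volume (cm^3).

    The clonogen density may be pinned here; by default it is taken from the
    model parameter set at evaluation time (it is a fitted quantity).
    """

    volume_cm3: float
    clonogen_density_per_cm3: float | None = None

    def __post_init__(self):
        if self.volume_cm3 <= 0:
            raise ValueError("volume_cm3 must be > 0")
        if self.clonogen_density_per_cm3 is not None and self.clonogen_density_per_cm3 <= 0:
            raise ValueError("clonogen_density_per_cm3 must be > 0")

    def k0(self, default_density_per_cm3: float) -> float:
        """Initial clonogen number K_0 = rho * V."""
        rho = (
            self.clonogen_density_per_cm3
            if self.clonogen_density_per_cm3 is not None
            else default_density_per_cm3
        )
        k0 = rho * self.volume_cm3
        if k0 < 1:
            raise ValueError("K_0 = rho * V must be >= 1")
        return k0


def tcp_gaussian(sf, k0: float, k_cr: float, sigma_k: float):
    """Gaussian-threshold TCP: 1 - Phi((K_0*sf - K_cr)/sigma_k).

    Evaluated with the complementary normal CDF, numerically stable far into
    either tail; clamped to [0, 1]. Vectorized over ``sf``.
    """
    if k0 <= 0 or k_cr <= 0 or sigma_k <= 0:
        raise ValueError("k0, k_cr and sigma_k must be > 0")
    sf = np.asarray(sf, dtype=float)
    if np.any(sf < 0):
        raise ValueError("sf must be >= 0")
    with np.errstate(over="ignore"):  # huge K_0*sf overflows to inf -> TCP 0
        x0 = (k0 * sf - k_cr) / sigma_k
    out = np.clip(ndtr(-x0), 0.0, 1.0)  # 1 - Phi(x0)
    return out if out.shape else float(out)


def tcp_poisson(sf, k0: float, mode: str = "poisson"):
    """Zero-surviving-clonogen TCP.

    ``mode="poisson"`` gives exp(-K_0*sf); ``mode="binomial"`` the exact
    (1 - sf)^K_0, which requires sf <= 1. The two agree closely whenever
    K_0 * sf^2 is small.
    """
    if k0 <= 0:
        raise ValueError("k0 must be > 0")
    sf = np.asarray(sf, dtype=float)
    if np.any(sf < 0):
        raise ValueError("sf must be >= 0")
    if mode == "poisson":
        with np.errstate(over="ignore"):  # huge K_0*sf overflows to inf -> TCP 0
            out = np.exp(-k0 * sf)
    elif mode == "binomial":
        if np.any(sf > 1):
            raise ValueError("binomial mode requires sf <= 1")
        out = np.exp(k0 * np.log1p(-np.minimum(sf, 1.0 - 1e-300)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.clip(out, 0.0, 1.0)
    return out if out.shape else float(out)


def tcp_time_curve(
    model: str,
    params,
    schedule: FractionationSchedule,
    tumor: TumorSpec,
    times_months,
):
    """TCP at each follow-up time (months since end of radiotherapy).

    ``model`` is ``"lqrg"`` (Gaussian TCP) or ``"lq"`` (Poisson TCP). Times
    must be sorted and non-negative; the returned series is non-increasing.
    """
    times = np.asarray(times_months, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    t_hours = months_to_hours(times)
    if model == "lqrg":
        if not isinstance(params, LQRGParams):
            raise ValueError("model 'lqrg' requires LQRGParams")
        sf = surviving_fraction_lqrg(params, schedule, t_hours)
        return tcp_gaussian(sf, tumor.k0(params.rho_per_cm3), params.k_cr, params.sigma_k)
    if model == "lq":
        if not isinstance(params, LQParams):
            raise ValueError("model 'lq' requires LQParams")
        sf = surviving_fraction_lq(params, schedule, t_hours)
        return tcp_poisson(sf, tumor.k0(params.rho_per_cm3))
    raise ValueError(f"unknown model {model!r}; expected 'lq' or 'lqrg'")
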