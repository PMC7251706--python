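"""Synthetic patient cohorts with the structure the analysis assumes.

The study cohort behind the packaged default parameters is not public, so
this module generates stand-in cohorts: three treatment groups defined by
their delivered-dose summaries, log-normal tumor volumes, failure times
drawn from the LQRG-implied survivor function TCP(t) by inverse-transform
sampling, and administrative right censoring with uniform staggered entry.

Only loco-regional failure is simulated (deaths and distant-only failures
are censoring in the LPFS definition, so they fold into the censoring
process). A single master seed fans out to per-patient substreams, keyed by
(group index, patient index), so a group's records do not change when other
groups are resized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell_survival import LQRGParams
from .schedule import FractionationSchedule, group_representative_schedule
from .survival_curves import PatientRecord
from .tcp import TumorSpec, tcp_time_curve

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "DEFAULT_COHORT_SPEC",
    "default_cohort_spec",
    "sample_event_time",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: size, schedule summary, tumor-volume distribution."""

    name: str
    size: int
    mean_total_dose_gy: float
    median_fraction_size_gy: float
    gtv_mean_cm3: float
    gtv_cv: float = 0.5

    def __post_init__(self):
        if self.size < 0:
            raise ValueError("group size must be >= 0")
        if self.mean_total_dose_gy <= 0 or self.median_fraction_size_gy <= 0:
            raise ValueError("dose summaries must be > 0")
        if self.gtv_mean_cm3 <= 0:
            raise ValueError("gtv_mean_cm3 must be > 0")
        if self.gtv_cv < 0:
            raise ValueError("gtv_cv must be >= 0")

    def schedule(self) -> FractionationSchedule:
        return group_representative_schedule(
            self.mean_total_dose_gy, self.median_fraction_size_gy
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "size": self.size,
            "mean_total_dose_gy": self.mean_total_dose_gy,
            "median_fraction_size_gy": self.median_fraction_size_gy,
            "gtv_mean_cm3": self.gtv_mean_cm3,
            "gtv_cv": self.gtv_cv,
        }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort blueprint: groups plus the censoring model.

    Censoring is administrative: patients enter uniformly over
    ``accrual_months`` and everyone is cut off ``horizon_months`` after the
    first entry, so censoring times are uniform on
    [horizon - accrual, horizon].
    """

    groups: tuple
    horizon_months: float = 70.0
    accrual_months: float = 41.0
    grid_step_months: float = 0.25
    per_patient_volumes: bool = False

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")
        if not (0 <= self.accrual_months < self.horizon_months):
            raise ValueError("accrual_months must lie in [0, horizon)")
        if self.grid_step_months <= 0:
            raise ValueError("grid_step_months must be > 0")

    def to_dict(self) -> dict:
        return {
            "groups": [g.to_dict() for g in self.groups],
            "horizon_months": self.horizon_months,
            "accrual_months": self.accrual_months,
            "grid_step_months": self.grid_step_months,
            "per_patient_volumes": self.per_patient_volumes,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        groups = tuple(GroupSpec(**g) for g in data["groups"])
        extra = {k: v for k, v in data.items() if k != "groups"}
        return cls(groups=groups, **extra)


def default_cohort_spec(sizes=(34, 34, 35), gtv_cv: float = 0.5, **kwargs) -> CohortSpec:
    """Three-group cohort emulating the packaged defaults' source cohort.

    Group summaries: mean GTV doses 62.92/64.07/62.89 Gy, median fraction
    sizes 2.1/2.4/2.8 Gy, mean GTV volumes 105.83/102.21/108.51 cm^3;
    default group sizes 34/34/35.
    """
    summaries = [
        ("A", 62.92, 2.1, 105.83),
        ("B", 64.07, 2.4, 102.21),
        ("C", 62.89, 2.8, 108.51),
    ]
    groups = tuple(
        GroupSpec(
            name=name,
            size=size,
            mean_total_dose_gy=dose,
            median_fraction_size_gy=frac,
            gtv_mean_cm3=vol,
            gtv_cv=gtv_cv,
        )
        for (name, dose, frac, vol), size in zip(summaries, sizes)
    )
    return CohortSpec(groups=groups, **kwargs)


DEFAULT_COHORT_SPEC = default_cohort_spec()


def sample_event_time(times_months, survival, uniform_draw: float) -> float:
    """Inverse-transform sample from a survivor curve given on a grid.

    ``survival`` must be non-increasing with S(0) <= 1. Returns ``inf``
    (no event within the grid horizon) when the draw falls below the curve's
    final value, the monotone-interpolated inverse otherwise; draws above
    S(0) map to an event at time 0 (the curve's initial deficit from 1 is a
    point mass at 0 in this model).
    """
    t = np.asarray(times_months, dtype=float)
    s = np.asarray(survival, dtype=float)
    if t.shape != s.shape or t.size < 2:
        raise ValueError("grid and survival must be equal-length with >= 2 points")
    if s[0] > 1.0 + 1e-12:
        raise ValueError("survival curve must start at or below 1")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("survival curve must be non-increasing")
    if not (0.0 <= uniform_draw <= 1.0):
        raise ValueError("uniform_draw must lie in [0, 1]")
    if uniform_draw < s[-1]:
        return float("inf")
    if uniform_draw >= s[0]:
        return float(t[0])
    # np.interp needs ascending x; survival is descending in t
    return float(np.interp(uniform_draw, s[::-1], t[::-1]))


def _lognormal_params(mean: float, cv: float):
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def simulate_cohort(spec: CohortSpec, params: LQRGParams | None = None, seed: int = 0):
    """Draw a synthetic cohort; returns a list of :class:`PatientRecord`.

    Per patient: the group-representative schedule, a log-normal GTV volume,
    an event time sampled from the LQRG TCP(t) curve (group mean volume by
    default; the patient's own volume when ``spec.per_patient_volumes``),
    censored at the patient's administrative cutoff. Deterministic per seed.
    """
    params = params if params is not None else LQRGParams()
    grid = np.arange(
        0.0, spec.horizon_months + spec.grid_step_months, spec.grid_step_months
    )
    records = []
    for gi, group in enumerate(spec.groups):
        if group.size == 0:
            continue
        schedule = group.schedule()
        group_curve = None
        if not spec.per_patient_volumes:
            group_curve = np.asarray(
                tcp_time_curve(
                    "lqrg", params, schedule, TumorSpec(group.gtv_mean_cm3), grid
                )
            )
        mu, sig = _lognormal_params(group.gtv_mean_cm3, group.gtv_cv)
        for pi in range(group.size):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(gi, pi))
            )
            volume = float(np.exp(rng.normal(mu, sig))) if group.gtv_cv > 0 else group.gtv_mean_cm3
            if spec.per_patient_volumes:
                curve = np.asarray(
                    tcp_time_curve("lqrg", params, schedule, TumorSpec(volume), grid)
                )
            else:
                curve = group_curve
            t_event = sample_event_time(grid, curve, float(rng.uniform()))
            entry = float(rng.uniform(0.0, spec.accrual_months)) if spec.accrual_months > 0 else 0.0
            t_censor = spec.horizon_months - entry
            if t_event <= t_censor:
                records.append(PatientRecord(group.name, volume, t_event, True))
            else:
                records.append(PatientRecord(group.name, volume, t_censor, False))
    return records
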