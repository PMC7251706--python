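"""Fractionated dose-delivery schedules.

A :class:`FractionationSchedule` records when each radiotherapy fraction
starts (hours from the first fraction), how much dose it delivers (Gy) and
how long delivery takes (hours; 0 means an instantaneous, "acute" exposure).
Together these define the dose-rate function R(u) that the dose-protraction
(Lea-Catcheside) factor integrates over, as well as the summary quantities
the cell-survival models need: total dose D, fraction count n and overall
treatment time T (start of first fraction to end of the last).

Schedules are immutable and hashable so that protraction-factor results can
be cached against them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

from ._units import HOURS_PER_DAY, hours_to_weeks

__all__ = [
    "FractionationSchedule",
    "build_uniform_schedule",
    "group_representative_schedule",
]


@dataclass(frozen=True)
class FractionationSchedule:
    """Timing and dose of every fraction in a radiotherapy course.

    Parameters
    ----------
    start_times_h
        Start time of each fraction in hours from the first fraction;
        strictly increasing, first entry 0 by convention (not enforced).
    doses_gy
        Dose per fraction in Gy; all strictly positive.
    durations_h
        Delivery duration of each fraction in hours; 0 means instantaneous.
        A fraction must finish before the next one starts.
    nominal_fraction_size_gy
        Optional record of the nominal (e.g. cohort-median) fraction size a
        representative schedule was built from.
    target_total_dose_gy
        Optional record of the total dose the schedule was built to deliver.
    """

    start_times_h: tuple
    doses_gy: tuple
    durations_h: tuple
    nominal_fraction_size_gy: float | None = None
    target_total_dose_gy: float | None = None

    def __post_init__(self):
        t = tuple(float(x) for x in self.start_times_h)
        d = tuple(float(x) for x in self.doses_gy)
        w = tuple(float(x) for x in self.durations_h)
        object.__setattr__(self, "start_times_h", t)
        object.__setattr__(self, "doses_gy", d)
        object.__setattr__(self, "durations_h", w)
        if not (len(t) == len(d) == len(w)):
            raise ValueError("start_times_h, doses_gy and durations_h must have equal length")
        if len(t) == 0:
            raise ValueError("schedule must contain at least one fraction")
        if any(x <= 0 for x in d):
            raise ValueError("all fraction doses must be > 0")
        if any(x < 0 for x in w):
            raise ValueError("fraction durations must be >= 0")
        if any(t2 <= t1 for t1, t2 in zip(t, t[1:])):
            raise ValueError("fraction start times must be strictly increasing")
        if any(t1 + w1 > t2 for t1, w1, t2 in zip(t, w, t[1:])):
            raise ValueError("a fraction's delivery overlaps the next fraction's start")

    # -- derived quantities -------------------------------------------------

    @property
    def n_fractions(self) -> int:
        return len(self.doses_gy)

    @property
    def total_dose_gy(self) -> float:
        """Total physical dose D (Gy)."""
        return float(sum(self.doses_gy))

    @property
    def overall_time_h(self) -> float:
        """Overall treatment time T: start of first to end of last fraction."""
        return (self.start_times_h[-1] + self.durations_h[-1]) - self.start_times_h[0]

    @property
    def overall_time_weeks(self) -> float:
        return hours_to_weeks(self.overall_time_h)

    @property
    def is_instantaneous(self) -> bool:
        return all(w == 0.0 for w in self.durations_h)

    @property
    def is_uniform(self) -> bool:
        """True when all fractions deliver the same dose."""
        d0 = self.doses_gy[0]
        return all(math.isclose(d, d0, rel_tol=1e-12, abs_tol=0.0) for d in self.doses_gy)

    @property
    def fraction_size_gy(self) -> float:
        """Uniform dose per fraction; raises for non-uniform schedules."""
        if not self.is_uniform:
            raise ValueError("schedule has non-uniform fraction sizes")
        return self.doses_gy[0]

    def with_total_dose(self, total_dose_gy: float) -> "FractionationSchedule":
        """Rescale all fraction doses to deliver ``total_dose_gy``."""
        if total_dose_gy <= 0:
            raise ValueError("total dose must be > 0")
        f = total_dose_gy / self.total_dose_gy
        return replace(self, doses_gy=tuple(d * f for d in self.doses_gy),
                       target_total_dose_gy=total_dose_gy)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "fractions": [
                {"t_start_h": t, "dose_gy": d, "duration_h": w}
                for t, d, w in zip(self.start_times_h, self.doses_gy, self.durations_h)
            ]
        }
        if self.nominal_fraction_size_gy is not None:
            out["nominal_fraction_size_gy"] = self.nominal_fraction_size_gy
        if self.target_total_dose_gy is not None:
            out["target_total_dose_gy"] = self.target_total_dose_gy
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "FractionationSchedule":
        fr = data["fractions"]
        return cls(
            start_times_h=tuple(f["t_start_h"] for f in fr),
            doses_gy=tuple(f["dose_gy"] for f in fr),
            durations_h=tuple(f.get("duration_h", 0.0) for f in fr),
            nominal_fraction_size_gy=data.get("nominal_fraction_size_gy"),
            target_total_dose_gy=data.get("target_total_dose_gy"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FractionationSchedule":
        return cls.from_dict(json.loads(s))

    # -- numpy views --------------------------------------------------------

    def start_times_array(self) -> np.ndarray:
        return np.asarray(self.start_times_h, dtype=float)

    def doses_array(self) -> np.ndarray:
        return np.asarray(self.doses_gy, dtype=float)

    def durations_array(self) -> np.ndarray:
        return np.asarray(self.durations_h, dtype=float)


def _weekday_offsets(n: int) -> list:
    """Day offset of fraction i under once-daily weekday-only delivery.

    Five fractions per 7-day week: days 0..4 treated, days 5-6 skipped.
    """
    return [7 * (i // 5) + (i % 5) for i in range(n)]


def build_uniform_schedule(
    n_fractions: int,
    dose_per_fraction_gy: float,
    interfraction_interval_h: float = HOURS_PER_DAY,
    fraction_duration_h: float = 0.0,
    weekday_only: bool = False,
) -> FractionationSchedule:
    """Build an equal-dose schedule delivered at a fixed interval.

    With ``weekday_only`` the interval is interpreted as the day length and
    fractions are laid out five per seven-day week (weekend gaps), the usual
    clinical once-daily pattern.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if dose_per_fraction_gy <= 0:
        raise ValueError("dose_per_fraction_gy must be > 0")
    if fraction_duration_h < 0:
        raise ValueError("fraction_duration_h must be >= 0")
    if interfraction_interval_h <= fraction_duration_h:
        raise ValueError("interfraction interval must exceed the fraction duration")

    if weekday_only:
        offsets = _weekday_offsets(n_fractions)
        times = tuple(interfraction_interval_h * o for o in offsets)
    else:
        times = tuple(interfraction_interval_h * i for i in range(n_fractions))
    return FractionationSchedule(
        start_times_h=times,
        doses_gy=(dose_per_fraction_gy,) * n_fractions,
        durations_h=(fraction_duration_h,) * n_fractions,
    )


def group_representative_schedule(
    mean_total_dose_gy: float,
    median_fraction_size_gy: float,
    fraction_duration_h: float = 0.0,
) -> FractionationSchedule:
    """Representative schedule for a treatment group known only by summary stats.

    The fraction count is the nearest integer to mean dose / median fraction
    size; fractions are instantaneous, once daily, weekdays only. The dose
    per fraction is set to ``mean_total_dose_gy / n`` so the schedule's total
    dose equals the group's mean delivered dose; the median fraction size is
    kept as the nominal fraction size.
    """
    if mean_total_dose_gy <= 0 or median_fraction_size_gy <= 0:
        raise ValueError("doses must be > 0")
    n = int(math.floor(mean_total_dose_gy / median_fraction_size_gy + 0.5))
    if n < 1:
        raise ValueError("fraction count rounds to zero; fraction size exceeds ~2x total dose")
    sched = build_uniform_schedule(
        n, mean_total_dose_gy / n,
        interfraction_interval_h=HOURS_PER_DAY,
        fraction_duration_h=fraction_duration_h,
        weekday_only=True,
    )
    return replace(
        sched,
        nominal_fraction_size_gy=median_fraction_size_gy,
        target_total_dose_gy=mean_total_dose_gy,
    )
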