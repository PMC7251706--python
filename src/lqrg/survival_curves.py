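"""Kaplan-Meier estimation of loco-regional progression-free survival.

Patient records carry the time from the end of radiotherapy to loco-regional
progression (event) or last follow-up (censored; deaths without loco-regional
progression count as censored). The product-limit estimator turns a group of
records into a right-continuous step curve LPFS(t) that the TCP models are
fitted against.

Estimation is delegated to :class:`lifelines.KaplanMeierFitter`; this module
wraps it in a light container with step-function sampling and per-record
fitting samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "PatientRecord",
    "SurvivalCurve",
    "km_estimate",
    "sample_curve",
    "lpfs_samples",
    "records_to_dataframe",
    "records_from_dataframe",
    "read_cohort_csv",
    "write_cohort_csv",
]


@dataclass(frozen=True)
class PatientRecord:
    """One (possibly synthetic) patient.

    ``time_months`` runs from the end of radiotherapy; ``event`` is True for
    loco-regional progression, False for censoring.
    """

    group: str
    gtv_cm3: float
    time_months: float
    event: bool

    def __post_init__(self):
        if self.time_months < 0:
            raise ValueError("time_months must be >= 0")
        if self.gtv_cm3 <= 0:
            raise ValueError("gtv_cm3 must be > 0")


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous product-limit survival curve.

    ``times`` are the distinct observed times (events and censorings),
    ``probs`` the survival probability just after each time, ``at_risk`` the
    number at risk just before it. S(t) = 1 for t before the first observed
    time. Optional Greenwood 95% confidence bands.
    """

    times: tuple
    probs: tuple
    at_risk: tuple
    conf_lower: tuple | None = None
    conf_upper: tuple | None = None

    def __post_init__(self):
        p = np.asarray(self.probs)
        if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.diff(p) > 1e-12)):
            raise ValueError("survival probabilities must be non-increasing within [0, 1]")

    @property
    def last_time(self) -> float:
        return self.times[-1]

    def sample(self, times_months, with_flags: bool = False):
        return sample_curve(self, times_months, with_flags=with_flags)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_months": self.times, "lpfs": self.probs, "at_risk": self.at_risk}
        )
        if self.conf_lower is not None:
            df["lpfs_ci_lower"] = self.conf_lower
            df["lpfs_ci_upper"] = self.conf_upper
        return df


def km_estimate(records, confidence_bands: bool = False) -> SurvivalCurve:
    """Product-limit LPFS estimate from patient records.

    Ties are handled the standard way: all events at a time are processed
    before censorings at the same time. Raises on an empty record list or
    negative times (enforced by :class:`PatientRecord`).
    """
    records = list(records)
    if not records:
        raise ValueError("record list must be non-empty")
    durations = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    times = np.unique(durations)
    probs = kmf.survival_function_at_times(times).to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
    kwargs = {}
    if confidence_bands:
        ci = kmf.confidence_interval_survival_function_
        lo = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
        hi = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
        kwargs = {"conf_lower": tuple(lo), "conf_upper": tuple(hi)}
    return SurvivalCurve(
        times=tuple(float(t) for t in times),
        probs=tuple(float(p) for p in probs),
        at_risk=tuple(int(a) for a in at_risk),
        **kwargs,
    )


def sample_curve(curve: SurvivalCurve, times_months, with_flags: bool = False):
    """Evaluate the step curve at arbitrary times (right-continuous lookup).

    Times before the first observed time give 1; times beyond the last
    observation return the last value, flagged as extrapolated when
    ``with_flags`` is set.
    """
    times = np.asarray(times_months, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    curve_t = np.asarray(curve.times)
    curve_p = np.concatenate([[1.0], np.asarray(curve.probs)])
    idx = np.searchsorted(curve_t, times, side="right")
    values = curve_p[idx]
    values = values if values.shape else float(values)
    if with_flags:
        extrapolated = times > curve.last_time
        return values, (extrapolated if np.shape(times) else bool(extrapolated))
    return values


def lpfs_samples(records) -> tuple:
    """(times, lpfs) fitting samples: one sample per patient record.

    Every record — event or censored — contributes the KM estimate at its own
    observation time, so the sample count equals the cohort size.
    """
    records = list(records)
    curve = km_estimate(records)
    times = np.sort(np.array([r.time_months for r in records], dtype=float))
    return times, np.asarray(sample_curve(curve, times), dtype=float)


# -- cohort (de)serialization ----------------------------------------------

_COLUMNS = ["group", "gtv_cm3", "time_months", "event"]


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.group, r.gtv_cm3, r.time_months, int(r.event)) for r in records],
        columns=_COLUMNS,
    )


def records_from_dataframe(df: pd.DataFrame) -> list:
    return [
        PatientRecord(
            group=str(row.group),
            gtv_cm3=float(row.gtv_cm3),
            time_months=float(row.time_months),
            event=bool(int(row.event)),
        )
        for row in df.itertuples(index=False)
    ]


def read_cohort_csv(path) -> list:
    return records_from_dataframe(pd.read_csv(path))


def write_cohort_csv(records, path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)
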