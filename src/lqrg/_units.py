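"""Time-unit constants.

All schedule arithmetic is carried out in hours; repopulation and
post-treatment growth terms are evaluated in days; clinical follow-up is
expressed in months. Conversions happen only through these constants.
"""

HOURS_PER_DAY = 24.0
DAYS_PER_WEEK = 7.0
HOURS_PER_WEEK = HOURS_PER_DAY * DAYS_PER_WEEK
DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375
HOURS_PER_MONTH = HOURS_PER_DAY * DAYS_PER_MONTH


def hours_to_days(hours: float) -> float:
    return hours / HOURS_PER_DAY


def months_to_hours(months):
    return months * HOURS_PER_MONTH


def hours_to_weeks(hours: float) -> float:
    return hours / HOURS_PER_WEEK
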