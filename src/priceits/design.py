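"""Segmented-regression design for a two-interruption interrupted time series.

The monthly outcome series is modelled as

    Y_t = b0 + b1*time_t + b2*OPIP_t + b3*time_after_OPIP_t
             + b4*SPS_t  + b5*time_after_SPS_t + b6*Feb_t + e_t

where ``time`` is a 1-based month counter from the window origin, OPIP and SPS
are indicators switching on *at* each intervention month, the two
``time_after`` counters equal 1 at their intervention month and increase by 1
per month thereafter, and ``Feb`` flags February (a short month with
systematically lower utilization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DESIGN_COLUMNS",
    "InterventionSchedule",
    "ScheduleError",
    "build_design_matrix",
]

#: Covariate order used everywhere downstream (beta[0] is the intercept).
DESIGN_COLUMNS = ["time", "opip", "time_after_opip", "sps", "time_after_sps", "feb"]


class ScheduleError(ValueError):
    """Raised for an inconsistent intervention schedule."""


def _as_period(ym) -> pd.Period:
    if isinstance(ym, pd.Period):
        return ym.asfreq("M")
    return pd.Period(ym, freq="M")


@dataclass(frozen=True)
class InterventionSchedule:
    """Observation window plus the two intervention dates.

    Parameters
    ----------
    origin
        First month of the window, e.g. ``"2009-01"``.
    n_months
        Window length (54 for the reference study: Jan 2009 - Jun 2013).
    opip_start
        First month of the prescriber-incentive program (OPIP), ``"2010-10"``.
    sps_start
        First month of the Single Price System price cut (SPS), ``"2012-04"``.
    """

    origin: str | pd.Period = "2009-01"
    n_months: int = 54
    opip_start: str | pd.Period = "2010-10"
    sps_start: str | pd.Period = "2012-04"

    def __post_init__(self):
        origin = _as_period(self.origin)
        opip = _as_period(self.opip_start)
        sps = _as_period(self.sps_start)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "opip_start", opip)
        object.__setattr__(self, "sps_start", sps)
        if self.n_months < 1:
            raise ScheduleError(f"n_months must be positive, got {self.n_months}")
        end = origin + self.n_months - 1
        if not (origin <= opip):
            raise ScheduleError(f"opip_start {opip} precedes window origin {origin}")
        if not (opip < sps):
            raise ScheduleError(f"sps_start {sps} must come after opip_start {opip}")
        if not (sps <= end):
            raise ScheduleError(f"sps_start {sps} lies outside the window (ends {end})")

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.origin, periods=self.n_months, freq="M")

    def month_index(self, ym) -> int:
        """1-based position of a calendar month inside the window."""
        return (_as_period(ym) - self.origin).n + 1

    @property
    def opip_month(self) -> int:
        return self.month_index(self.opip_start)

    @property
    def sps_month(self) -> int:
        return self.month_index(self.sps_start)


def build_design_matrix(schedule: InterventionSchedule) -> pd.DataFrame:
    """Build the covariate matrix, one row per month of the window.

    The intervention month itself is coded as post-intervention: the indicator
    is 1 and the elapsed-time counter is 1 at the start month (so in the
    reference window ``time_after_sps`` runs 1 in April 2012 to 15 in June
    2013, and ``time_after_opip`` runs 1 in October 2010 to 33 in June 2013).

    Returns a DataFrame indexed by calendar month (``PeriodIndex``) with the
    columns in :data:`DESIGN_COLUMNS`; the intercept is added at fit time.
    """
    months = schedule.months
    time = pd.RangeIndex(1, schedule.n_months + 1)
    k_opip = schedule.opip_month
    k_sps = schedule.sps_month
    t = time.to_series().to_numpy()
    X = pd.DataFrame(
        {
            "time": t,
            "opip": (t >= k_opip).astype(int),
            "time_after_opip": (t - (k_opip - 1)).clip(min=0),
            "sps": (t >= k_sps).astype(int),
            "time_after_sps": (t - (k_sps - 1)).clip(min=0),
            "feb": (months.month == 2).astype(int),
        },
        index=months,
    )
    X.index.name = "month"
    return X
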