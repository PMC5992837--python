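"""Cohort selection and monthly aggregation of claims.

The study cohort is every adult (>= 20 years) with at least one outpatient
claim carrying a diabetes diagnosis (ICD-10 category E11 or E14, matched on
the 3-character prefix) during the index window, excluding claims from
out-of-scope institution types. Claims for cohort members are then rolled up
into five monthly outcome series per price group: total antidiabetic cost,
total defined daily doses (DDD), distinct treated patients, and the two
per-patient ratios.

DDD convention: quantity divided by the WHO DDD units when available,
otherwise by the adult standard daily dose (the fallback used for items such
as fixed-dose combinations without an assigned DDD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DrugEntry

__all__ = [
    "AggregationError",
    "ClassificationError",
    "MonthlyOutcomeSeries",
    "OUTCOMES",
    "select_cohort",
    "compute_ddd",
    "aggregate_monthly",
    "descriptive_summary",
    "write_series",
    "read_series",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("cost_total", "ddd_total", "n_patients", "cost_per_patient", "ddd_per_patient")
SERIES_GROUPS = ("overall", "reduced", "constant")
EXCLUDED_INSTITUTION = "excluded_type"


class AggregationError(ValueError):
    pass


class ClassificationError(KeyError):
    """A drug could not be classified (missing dose fields or registry row)."""


@dataclass
class MonthlyOutcomeSeries:
    """A monthly series for one outcome x price-group combination.

    ``values`` has one entry per month from ``origin``; undefined per-patient
    months (no treated patients) are NaN. ``n_patients`` values are
    non-negative integers stored as floats for uniformity.
    """

    outcome: str
    group: str
    origin: pd.Period
    values: np.ndarray

    def __post_init__(self):
        self.origin = pd.Period(self.origin, freq="M")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.origin, periods=len(self.values), freq="M")

    def values_array(self) -> np.ndarray:
        return self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.months.year,
                "month": self.months.month,
                "value": self.values,
            }
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.months, name=f"{self.outcome}:{self.group}")


def write_series(series: MonthlyOutcomeSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path, outcome: str, group: str) -> MonthlyOutcomeSeries:
    df = pd.read_csv(path)
    missing = {"year", "month", "value"} - set(df.columns)
    if missing:
        raise AggregationError(f"{path}: missing columns {sorted(missing)}")
    origin = pd.Period(year=int(df.year.iloc[0]), month=int(df.month.iloc[0]), freq="M")
    return MonthlyOutcomeSeries(outcome=outcome, group=group, origin=origin, values=df.value.to_numpy())


def _service_month(claims: pd.DataFrame) -> pd.Series:
    """Calendar month of each claim; malformed dates are rejected and logged."""
    dates = pd.to_datetime(claims["service_date"], format="%Y-%m-%d", errors="coerce")
    bad = dates.isna()
    if bad.any():
        logger.warning("rejected %d claim(s) with malformed service_date", int(bad.sum()))
    return dates.dt.to_period("M")


def select_cohort(
    claims: pd.DataFrame,
    index_window=("2010-01", "2012-12"),
    min_age: int = 20,
    diagnosis_codes=("E11", "E14"),
) -> set:
    """Patients with a qualifying outpatient diabetes claim in the window.

    A claim qualifies if it is outpatient, not from an excluded institution
    type, falls inside ``index_window``, its diagnosis matches one of
    ``diagnosis_codes`` on the 3-character ICD-10 category prefix, and the
    patient is at least ``min_age`` at that claim. Empty input yields an
    empty cohort.
    """
    if claims.empty:
        return set()
    start, end = (pd.Period(p, freq="M") for p in index_window)
    month = _service_month(claims)
    dx_prefix = claims["diagnosis_code"].astype("string").str.slice(0, 3)
    ok = (
        month.notna()
        & (month >= start)
        & (month <= end)
        & (claims["setting"] == "outpatient")
        & (claims["institution_type"] != EXCLUDED_INSTITUTION)
        & dx_prefix.isin(set(diagnosis_codes))
        & (claims["age"] >= min_age)
    )
    return set(claims.loc[ok, "patient_id"])


def compute_ddd(entry: DrugEntry, quantity: float) -> float:
    """Defined daily doses for a dispensed quantity of one drug.

    quantity / WHO DDD units when the drug has an assigned DDD, else
    quantity / adult standard daily dose. Raises
    :class:`ClassificationError` naming the drug when neither is available.
    """
    if quantity < 0:
        raise AggregationError(f"negative quantity {quantity} for {entry.code}")
    if entry.who_ddd_units is not None:
        return quantity / entry.who_ddd_units
    if entry.standard_daily_dose_units is not None:
        return quantity / entry.standard_daily_dose_units
    raise ClassificationError(
        f"drug {entry.code}: no WHO DDD and no standard daily dose"
    )


def _registry_lookup(registry) -> dict[str, DrugEntry]:
    if isinstance(registry, dict):
        return registry
    return {e.code: e for e in registry}


def aggregate_monthly(
    claims: pd.DataFrame,
    cohort: set,
    registry,
    origin=None,
    n_months: int | None = None,
) -> dict[tuple[str, str], MonthlyOutcomeSeries]:
    """Roll cohort members' antidiabetic claims into monthly outcome series.

    Returns all five outcomes for each of the groups overall / reduced /
    constant (overall = union of the two groups; its patient count is the
    distinct count, not the sum). Per-patient values are NaN in months with
    no treated patients. Claims whose drug code is absent from the registry
    raise an error listing the offending codes.
    """
    lookup = _registry_lookup(registry)
    month = _service_month(claims)
    drugged = claims["drug_code"].notna()
    unknown = sorted(set(claims.loc[drugged, "drug_code"]) - set(lookup))
    if unknown:
        raise AggregationError(f"drug codes missing from the registry: {unknown}")

    rows = claims.loc[
        drugged
        & claims["patient_id"].isin(cohort)
        & (claims["setting"] == "outpatient")
        & (claims["institution_type"] != EXCLUDED_INSTITUTION)
        & month.notna()
    ].copy()
    rows["month"] = month[rows.index]
    rows["group"] = rows["drug_code"].map(lambda c: lookup[c].group)
    rows["ddd"] = [
        compute_ddd(lookup[c], q) for c, q in zip(rows["drug_code"], rows["quantity"])
    ]

    if origin is None:
        if rows.empty:
            raise AggregationError("no aggregatable claims and no window given")
        origin = rows["month"].min()
    origin = pd.Period(origin, freq="M")
    if n_months is None:
        n_months = (rows["month"].max() - origin).n + 1
    months = pd.period_range(origin, periods=n_months, freq="M")

    out: dict[tuple[str, str], MonthlyOutcomeSeries] = {}
    for group in SERIES_GROUPS:
        sub = rows if group == "overall" else rows[rows["group"] == group]
        cost = sub.groupby("month")["cost"].sum().reindex(months, fill_value=0.0)
        ddd = sub.groupby("month")["ddd"].sum().reindex(months, fill_value=0.0)
        npat = (
            sub.groupby("month")["patient_id"].nunique().reindex(months, fill_value=0)
        ).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpp = np.where(npat > 0, cost / npat, np.nan)
            dpp = np.where(npat > 0, ddd / npat, np.nan)
        values = {
            "cost_total": cost.to_numpy(),
            "ddd_total": ddd.to_numpy(),
            "n_patients": npat.to_numpy(),
            "cost_per_patient": cpp,
            "ddd_per_patient": dpp,
        }
        for outcome in OUTCOMES:
            out[(outcome, group)] = MonthlyOutcomeSeries(
                outcome=outcome, group=group, origin=origin, values=values[outcome]
            )
    return out


def descriptive_summary(series_map, periods) -> pd.DataFrame:
    """Mean +/- sample SD of monthly values per reporting period.

    ``periods`` is a list of ``(label, start, end)`` month ranges (inclusive,
    non-overlapping). SD uses the n-1 denominator and is reported missing for
    single-month periods.
    """
    bounds = []
    for label, start, end in periods:
        s, e = pd.Period(start, freq="M"), pd.Period(end, freq="M")
        if e < s:
            raise AggregationError(f"period {label!r} ends before it starts")
        bounds.append((label, s, e))
    for (l1, s1, e1), (l2, s2, e2) in zip(bounds, bounds[1:]):
        if s2 <= e1:
            raise AggregationError(f"periods {l1!r} and {l2!r} overlap")

    items = series_map.items() if isinstance(series_map, dict) else (
        ((s.outcome, s.group), s) for s in series_map
    )
    rows = []
    for (outcome, group), series in items:
        values = series.to_series()
        for label, s, e in bounds:
            window = values[(values.index >= s) & (values.index <= e)].dropna()
            mean = float(window.mean()) if len(window) else np.nan
            sd = float(window.std(ddof=1)) if len(window) >= 2 else np.nan
            rows.append(
                {
                    "outcome": outcome,
                    "group": group,
                    "period": label,
                    "n_months": len(window),
                    "mean": mean,
                    "sd": sd,
                }
            )
    return pd.DataFrame(rows)
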