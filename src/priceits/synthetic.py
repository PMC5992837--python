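"""Synthetic claims, outcome series and procedure events with known truth.

The real study population (every Korean diabetic outpatient's claims,
2009-2013) is confidential, so this module emulates its statistical
structure at three levels:

1. **Aggregate monthly outcome series** following the segmented-regression
   data-generating process ``y_t = x_t' beta + e_t`` with strictly stationary
   AR(1) errors (``e_1`` drawn from the stationary distribution, variance
   ``noise_sd^2 / (1 - rho^2)``), so the estimation model is exactly correct.
2. **Patient-level claims** (diagnosis codes E11/E14 plus deliberate
   contamination, ages with an under-20 fraction, outpatient setting, NHI /
   Medical Aid mix, drug codes split into reduced- vs constant-price groups)
   whose monthly aggregates reproduce configured target series: exactly for
   distinct-patient counts, and to within per-record whole-KRW rounding for
   cost and DDD totals.
3. **Monthly complication-procedure events** as Poisson counts at configured
   per-1000-patient rates per reporting period.

One integer seed drives everything: independent substreams are derived with
``numpy.random.SeedSequence(seed, spawn_key=(crc32(label),))`` so each
generator (series, claims, procedures) is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import InterventionSchedule, build_design_matrix
from . import reference

__all__ = [
    "ConfigurationError",
    "DrugEntry",
    "SeriesSpec",
    "SyntheticConfig",
    "make_default_registry",
    "registry_frame",
    "generate_monthly_series",
    "generate_claims",
    "generate_procedure_incidents",
]

GROUPS = ("reduced", "constant")
INSTITUTION_TYPES = (
    "clinic",
    "nursing_home",
    "teaching_hospital",
    "general_hospital",
    "other_hospital",
)

CLAIMS_COLUMNS = [
    "patient_id",
    "age",
    "service_date",
    "setting",
    "institution_type",
    "insurance",
    "diagnosis_code",
    "drug_code",
    "quantity",
    "cost",
    "copayment",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DrugEntry:
    """One antidiabetic ingredient in the registry.

    Exactly one of ``who_ddd_units`` / ``standard_daily_dose_units`` may be
    absent (the latter is the fallback when no WHO defined daily dose
    exists, e.g. fixed-dose combinations). Reduced-price drugs must have
    ``unit_price_post < unit_price_pre``; constant-price drugs keep their
    price.
    """

    code: str
    group: str  # "reduced" | "constant"
    unit_price_pre: float
    unit_price_post: float
    who_ddd_units: float | None = None
    standard_daily_dose_units: float | None = None
    market_entry_month: int | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConfigurationError(f"{self.code}: unknown group {self.group!r}")
        if self.unit_price_pre <= 0 or self.unit_price_post <= 0:
            raise ConfigurationError(f"{self.code}: prices must be positive")
        if self.who_ddd_units is None and self.standard_daily_dose_units is None:
            raise ConfigurationError(
                f"{self.code}: needs who_ddd_units or standard_daily_dose_units"
            )
        if self.group == "reduced" and not self.unit_price_post < self.unit_price_pre:
            raise ConfigurationError(
                f"{self.code}: reduced-price drug must have post < pre price"
            )
        if self.group == "constant" and self.unit_price_post != self.unit_price_pre:
            raise ConfigurationError(
                f"{self.code}: constant-price drug must keep its price"
            )

    @property
    def ddd_units(self) -> float:
        """Units per defined (or fallback standard) daily dose."""
        return (
            self.who_ddd_units
            if self.who_ddd_units is not None
            else self.standard_daily_dose_units
        )


@dataclass(frozen=True)
class SeriesSpec:
    """True data-generating parameters for one outcome x group series."""

    beta: tuple  # (b0..b6)
    rho: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if len(self.beta) != 7:
            raise ConfigurationError("beta must have 7 entries (b0..b6)")
        if not -1 < self.rho < 1:
            raise ConfigurationError(f"ar1 rho must lie in (-1, 1), got {self.rho}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _default_series() -> dict:
    """Study-condition truth: the published estimates per outcome x group.

    AR(1) rho is the reported coefficient (0 for OLS rows); noise_sd is 2% of
    the baseline level |b0|, giving within-period dispersion comparable to
    the published descriptive SDs.
    """
    out = {}
    for outcome, groups in reference.REFERENCE_FITS.items():
        for group, info in groups.items():
            rho = info["rho"] if info["rho"] is not None else 0.0
            out[(outcome, group)] = SeriesSpec(
                beta=tuple(float(b) for b in info["beta"]),
                rho=float(rho),
                noise_sd=0.02 * abs(float(info["beta"][0])),
            )
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth configuration for the generators.

    Defaults describe the reference study's conditions: a 54-month window
    from January 2009 with interruptions in October 2010 (month 22) and
    April 2012 (month 40), a four-million-patient diabetic outpatient pool
    with an 8% Medical Aid share, ages ~ Normal(60, 13) truncated at 20
    (plus a small deliberate under-20 contamination so the age filter has
    work to do), an E11-dominant diagnosis mix, and per-period complication
    rates equal to the published table. ``scaled()`` shrinks the patient
    pool for tractable claims-level runs without touching rates or
    coefficients of per-patient structure.
    """

    schedule: InterventionSchedule = field(default_factory=InterventionSchedule)
    series: dict = field(default_factory=_default_series)
    n_patients: int = 4_000_000
    medaid_fraction: float = 0.08
    age_mean: float = 60.0
    age_sd: float = 13.0
    under20_fraction: float = 0.01
    diagnosis_mix: dict = field(
        default_factory=lambda: {"E11": 0.85, "E14": 0.12, "other": 0.03}
    )
    complication_rates: dict = field(
        default_factory=lambda: {k: list(v) for k, v in reference.COMPLICATION_RATES.items()}
    )
    complication_period_months: int = 12
    copay_rate_nhi: float = 0.30
    copay_rate_medaid: float = 0.05
    #: multiplier from series units to raw claim units (the reference
    #: coefficients are printed in billion KRW / million DDDs / persons)
    unit_scale: dict = field(
        default_factory=lambda: {"cost_total": 1e9, "ddd_total": 1e6, "n_patients": 1.0}
    )
    index_window: tuple = ("2010-01", "2012-12")
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for name, p in (
            ("medaid_fraction", self.medaid_fraction),
            ("under20_fraction", self.under20_fraction),
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        total = sum(self.diagnosis_mix.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"diagnosis_mix must sum to 1, sums to {total}")
        if any(v < 0 for v in self.diagnosis_mix.values()):
            raise ConfigurationError("diagnosis_mix proportions must be >= 0")
        for cat, rates in self.complication_rates.items():
            if any(r < 0 for r in rates):
                raise ConfigurationError(f"negative complication rate for {cat!r}")
        for key, spec in self.series.items():
            if not isinstance(spec, SeriesSpec):
                raise ConfigurationError(f"series[{key!r}] must be a SeriesSpec")

    @property
    def n_months(self) -> int:
        return self.schedule.n_months

    def scaled(self, factor: float) -> "SyntheticConfig":
        """Shrink the cohort (and count/total series) by ``factor``.

        Patient-count and total cost/DDD coefficients scale linearly with the
        pool; per-patient series are size-invariant and stay unchanged.
        """
        if not 0 < factor <= 1:
            raise ConfigurationError(f"scale factor must be in (0, 1], got {factor}")
        series = {}
        for key, spec in self.series.items():
            outcome = key[0]
            if outcome in ("n_patients", "cost_total", "ddd_total"):
                series[key] = replace(
                    spec,
                    beta=tuple(b * factor for b in spec.beta),
                    noise_sd=spec.noise_sd * factor,
                )
            else:
                series[key] = spec
        return replace(
            self,
            series=series,
            n_patients=max(1, int(round(self.n_patients * factor))),
        )


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))
    )


def make_default_registry(n_drugs: int = 97, n_reduced: int = 32, seed: int = 20120401) -> list[DrugEntry]:
    """Deterministic registry mirroring the study's ingredient counts.

    97 ingredient codes of which 32 had their price cut (to 70% of the
    pre-cut price here); roughly one in five entries lacks a WHO DDD and
    carries the adult standard-daily-dose fallback instead.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_drugs):
        group = "reduced" if i < n_reduced else "constant"
        pre = float(np.round(rng.uniform(100, 1500), 0))
        post = float(np.round(pre * 0.7, 0)) if group == "reduced" else pre
        ddd = float(rng.choice([0.5, 1.0, 2.0, 3.0]))
        use_fallback = rng.random() < 0.2
        entries.append(
            DrugEntry(
                code=f"D{i + 1:03d}",
                group=group,
                unit_price_pre=pre,
                unit_price_post=post,
                who_ddd_units=None if use_fallback else ddd,
                standard_daily_dose_units=ddd if use_fallback else None,
            )
        )
    return entries


def registry_frame(registry: list[DrugEntry]) -> pd.DataFrame:
    """Registry as a DataFrame (the on-disk representation)."""
    return pd.DataFrame(
        [
            {
                "code": e.code,
                "group": e.group,
                "unit_price_pre": e.unit_price_pre,
                "unit_price_post": e.unit_price_post,
                "who_ddd_units": e.who_ddd_units,
                "standard_daily_dose_units": e.standard_daily_dose_units,
                "market_entry_month": e.market_entry_month,
            }
            for e in registry
        ]
    )


def generate_monthly_series(config: SyntheticConfig, outcome: str, group: str = "overall"):
    """One monthly outcome series from the segmented AR(1) truth.

    Returns a :class:`~priceits.cohort.MonthlyOutcomeSeries`. With
    ``noise_sd = 0`` the series is the deterministic trend ``x_t' beta``.
    Deterministic given ``config.seed`` (per-series substream).
    """
    from .cohort import MonthlyOutcomeSeries  # local import to avoid a cycle

    key = (outcome, group)
    if key not in config.series:
        raise ConfigurationError(f"no series configuration for {key!r}")
    spec = config.series[key]
    X = build_design_matrix(config.schedule)
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    trend = Xc @ np.asarray(spec.beta, dtype=float)
    eps = _ar1_noise(
        _substream(config.seed, f"series:{outcome}:{group}"),
        config.n_months,
        spec.rho,
        spec.noise_sd,
    )
    return MonthlyOutcomeSeries(
        outcome=outcome,
        group=group,
        origin=config.schedule.origin,
        values=trend + eps,
    )


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    u = rng.normal(0.0, sd, size=n)
    e = np.empty(n)
    e[0] = u[0] / np.sqrt(1.0 - rho * rho)  # stationary start
    for t in range(1, n):
        e[t] = rho * e[t - 1] + u[t]
    return e


def _patient_pool(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    ids = np.array([f"P{i:07d}" for i in range(1, n + 1)])
    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    while True:  # truncate at 20 by resampling
        bad = ages < 20
        if not bad.any():
            break
        ages[bad] = rng.normal(config.age_mean, config.age_sd, size=int(bad.sum()))
    ages = np.round(ages).astype(int)
    under20 = rng.random(n) < config.under20_fraction
    ages[under20] = rng.integers(5, 20, size=int(under20.sum()))
    dx_labels = list(config.diagnosis_mix)
    dx_probs = np.array([config.diagnosis_mix[k] for k in dx_labels], dtype=float)
    dx = rng.choice(dx_labels, size=n, p=dx_probs / dx_probs.sum())
    insurance = np.where(rng.random(n) < config.medaid_fraction, "MedAid", "NHI")
    return pd.DataFrame(
        {"patient_id": ids, "age": ages, "diagnosis": dx, "insurance": insurance}
    )


def _target_counts(config: SyntheticConfig, group: str, n_eligible: int) -> np.ndarray:
    """Realized monthly treated-patient targets (the noisy series, rounded)."""
    if ("n_patients", group) not in config.series:
        raise ConfigurationError(f"no ('n_patients', {group!r}) series configured")
    values = generate_monthly_series(config, "n_patients", group).values
    scale = config.unit_scale.get("n_patients", 1.0)
    counts = np.rint(np.clip(values, 0.0, None) * scale).astype(int)
    if counts.max() > n_eligible:
        raise ConfigurationError(
            f"target {group} patient count {counts.max()} exceeds the eligible "
            f"pool of {n_eligible}; increase n_patients"
        )
    return counts


def _target_totals(
    config: SyntheticConfig, outcome: str, group: str, raw: bool = False
) -> np.ndarray:
    """Realized monthly totals the claims must aggregate back to."""
    if (outcome, group) not in config.series:
        raise ConfigurationError(f"no ({outcome!r}, {group!r}) series configured")
    values = generate_monthly_series(config, outcome, group).values
    scale = config.unit_scale.get(outcome, 1.0) if raw else 1.0
    return np.clip(values, 0.0, None) * scale


def generate_claims(config: SyntheticConfig, registry: list[DrugEntry]) -> pd.DataFrame:
    """Patient-level prescription claims matching the configured aggregates.

    Per month, disjoint sets of distinct eligible patients (age >= 20,
    diagnosis E11/E14) are drawn for the reduced- and constant-price groups
    at exactly the configured target counts; each selected patient receives
    one outpatient antidiabetic claim. Record quantities split the group's
    target DDD total equally; record cost is ``round(quantity x
    era-appropriate unit price)`` in whole KRW, so monthly cost totals match
    the implied target to within one KRW per record. Contamination rows
    (under-20 or non-diabetes patients, inpatient episodes, excluded
    institution types) are emitted deliberately so cohort filters are
    exercised. A final pass guarantees every treated patient has at least one
    qualifying outpatient diagnosis claim inside the index window.
    """
    if not registry:
        raise ConfigurationError("registry must be non-empty")
    rng = _substream(config.seed, "claims")
    pool = _patient_pool(config, rng)
    eligible = pool[(pool.age >= 20) & pool.diagnosis.isin(["E11", "E14"])]
    contaminated = pool.drop(eligible.index)
    by_group = {g: [e for e in registry if e.group == g] for g in GROUPS}
    for g, entries in by_group.items():
        if not entries:
            raise ConfigurationError(f"registry has no {g!r}-group drugs")

    months = config.schedule.months
    sps_k = config.schedule.sps_month
    counts = {g: _target_counts(config, g, len(eligible)) for g in GROUPS}
    if (counts["reduced"] + counts["constant"]).max() > len(eligible):
        raise ConfigurationError(
            "combined monthly group targets exceed the eligible pool; "
            "increase n_patients"
        )
    ddd_targets = {g: _target_totals(config, "ddd_total", g, raw=True) for g in GROUPS}

    elig_ids = eligible.patient_id.to_numpy()
    attrs = pool.set_index("patient_id")
    records: list[dict] = []
    for m, month in enumerate(months):
        era_post = (m + 1) >= sps_k
        perm = rng.permutation(len(elig_ids))
        offset = 0
        day_cycle = 0
        for g in GROUPS:
            k = counts[g][m]
            if k == 0:
                continue
            chosen = elig_ids[perm[offset : offset + k]]
            offset += k
            drugs = by_group[g]
            ddd_share = ddd_targets[g][m] / k
            days = rng.integers(1, 29, size=k)
            inst = rng.choice(INSTITUTION_TYPES, size=k)
            sub9 = rng.random(k) < 0.5  # half the codes carry a sub-code
            for j, pid in enumerate(chosen):
                entry = drugs[(m + j) % len(drugs)]
                quantity = ddd_share * entry.ddd_units
                price = entry.unit_price_post if era_post else entry.unit_price_pre
                cost = float(np.rint(quantity * price))
                pa = attrs.loc[pid]
                rate = (
                    config.copay_rate_medaid
                    if pa.insurance == "MedAid"
                    else config.copay_rate_nhi
                )
                dx = pa.diagnosis + (".9" if sub9[j] else "")
                records.append(
                    {
                        "patient_id": pid,
                        "age": int(pa.age),
                        "service_date": f"{month.year:04d}-{month.month:02d}-{days[j]:02d}",
                        "setting": "outpatient",
                        "institution_type": inst[j],
                        "insurance": pa.insurance,
                        "diagnosis_code": dx,
                        "drug_code": entry.code,
                        "quantity": float(quantity),
                        "cost": cost,
                        "copayment": float(np.rint(cost * rate)),
                    }
                )
            day_cycle += 1

    records.extend(_contamination_records(config, rng, contaminated, eligible, months))
    claims = pd.DataFrame(records, columns=CLAIMS_COLUMNS)
    claims = _ensure_index_window_dx(config, rng, claims, attrs)
    return claims.reset_index(drop=True)


def _contamination_records(config, rng, contaminated, eligible, months) -> list[dict]:
    """Filter fodder: non-cohort patients plus inpatient / excluded-type rows."""
    out = []
    dx_map = {"other": "I10", "E11": "E11", "E14": "E14"}
    for _, row in contaminated.iterrows():
        month = months[rng.integers(0, len(months))]
        day = int(rng.integers(1, 29))
        dx = dx_map.get(row.diagnosis, "I10")
        if row.diagnosis in ("E11", "E14") and row.age < 20:
            dx = row.diagnosis  # under-age diabetics: removed by the age filter
        out.append(
            {
                "patient_id": row.patient_id,
                "age": int(row.age),
                "service_date": f"{month.year:04d}-{month.month:02d}-{day:02d}",
                "setting": "outpatient",
                "institution_type": str(rng.choice(INSTITUTION_TYPES)),
                "insurance": row.insurance,
                "diagnosis_code": dx,
                "drug_code": None,
                "quantity": 0.0,
                "cost": float(rng.integers(5000, 20000)),
                "copayment": 0.0,
            }
        )
    # a few inpatient and excluded-institution diagnosis-only rows
    n_extra = max(1, len(eligible) // 50)
    extra_ids = eligible.patient_id.to_numpy()[
        rng.integers(0, len(eligible), size=n_extra)
    ]
    for pid in extra_ids:
        month = months[rng.integers(0, len(months))]
        row = eligible[eligible.patient_id == pid].iloc[0]
        inpatient = rng.random() < 0.5
        out.append(
            {
                "patient_id": pid,
                "age": int(row.age),
                "service_date": f"{month.year:04d}-{month.month:02d}-{int(rng.integers(1, 29)):02d}",
                "setting": "inpatient" if inpatient else "outpatient",
                "institution_type": "excluded_type" if not inpatient else str(rng.choice(INSTITUTION_TYPES)),
                "insurance": row.insurance,
                "diagnosis_code": row.diagnosis,
                "drug_code": None,
                "quantity": 0.0,
                "cost": float(rng.integers(10000, 50000)),
                "copayment": 0.0,
            }
        )
    return out


def _ensure_index_window_dx(config, rng, claims: pd.DataFrame, attrs: pd.DataFrame) -> pd.DataFrame:
    """Give every treated patient a qualifying claim in the index window."""
    start, end = (pd.Period(p, freq="M") for p in config.index_window)
    month = claims.service_date.str.slice(0, 7).map(lambda s: pd.Period(s, freq="M"))
    treated = set(claims.loc[claims.drug_code.notna(), "patient_id"])
    qualifying = set(
        claims.loc[
            (claims.setting == "outpatient")
            & (claims.institution_type != "excluded_type")
            & claims.diagnosis_code.str.slice(0, 3).isin(["E11", "E14"])
            & (month >= start)
            & (month <= end),
            "patient_id",
        ]
    )
    missing = sorted(treated - qualifying)
    if not missing:
        return claims
    extra = []
    span = (end - start).n + 1
    for pid in missing:
        pa = attrs.loc[pid]
        p = start + int(rng.integers(0, span))
        extra.append(
            {
                "patient_id": pid,
                "age": int(pa.age),
                "service_date": f"{p.year:04d}-{p.month:02d}-15",
                "setting": "outpatient",
                "institution_type": "clinic",
                "insurance": pa.insurance,
                "diagnosis_code": pa.diagnosis,
                "drug_code": None,
                "quantity": 0.0,
                "cost": 10000.0,
                "copayment": 0.0,
            }
        )
    return pd.concat([claims, pd.DataFrame(extra, columns=CLAIMS_COLUMNS)], ignore_index=True)


def generate_procedure_incidents(config: SyntheticConfig) -> pd.DataFrame:
    """Monthly complication-procedure counts per category (Poisson).

    The mean for month m in reporting period p is
    ``rate[p] / 1000 * n_patients``; the final part-period reuses the last
    configured rate. Returns a tidy frame (month, category, rate, count).
    Deterministic given ``config.seed``.
    """
    if not config.complication_rates:
        raise ConfigurationError("complication_rates must name at least one category")
    rng = _substream(config.seed, "procedures")
    months = config.schedule.months
    plen = config.complication_period_months
    rows = []
    for cat in sorted(config.complication_rates):
        rates = config.complication_rates[cat]
        for m, month in enumerate(months):
            p = min(m // plen, len(rates) - 1)
            lam = rates[p] / 1000.0 * config.n_patients
            rows.append(
                {
                    "month": str(month),
                    "category": cat,
                    "rate_per_1000": rates[p],
                    "count": int(rng.poisson(lam)),
                }
            )
    return pd.DataFrame(rows)
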