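"""Configuration-driven end-to-end runner: simulate -> aggregate -> fit ->
effects -> reports.

A run takes its data from exactly one of three sources: a synthetic
generation block, a claims file (plus registry), or pre-aggregated monthly
series files. Every stage writes delimited text under the output directory,
plus a machine-readable manifest (config hash, seed, package versions) that
suffices to reproduce the run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_pkg_version = "0.1.0"

from .cohort import (
    AggregationError,
    MonthlyOutcomeSeries,
    OUTCOMES,
    aggregate_monthly,
    descriptive_summary,
    read_series,
    select_cohort,
    write_series,
)
from .design import InterventionSchedule, build_design_matrix
from .effects import annual_growth, counterfactual_series, forecast_band, percent_effect
from .estimation import dw_pvalue, fit_ar1_ml, fit_ols, select_model, white_noise_check
from .synthetic import (
    CLAIMS_COLUMNS,
    ConfigurationError,
    SyntheticConfig,
    generate_claims,
    generate_monthly_series,
    generate_procedure_incidents,
    make_default_registry,
    registry_frame,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "validate_inputs", "coefficient_table"]

logger = logging.getLogger(__name__)

SERIES_GROUPS = ("overall", "reduced", "constant")


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Exactly one data source: ``synthetic`` config, or ``claims_path`` (+
    ``registry_path``), or ``series_dir`` holding ``<outcome>__<group>.csv``
    files. Analysis options cover the model-choice policy, effect horizons,
    band level and white-noise max lag.
    """

    out_dir: Path
    schedule: InterventionSchedule = field(default_factory=InterventionSchedule)
    synthetic: SyntheticConfig | None = None
    claims_path: Path | None = None
    registry_path: Path | None = None
    series_dir: Path | None = None
    outcomes: tuple = OUTCOMES
    groups: tuple = SERIES_GROUPS
    horizons: tuple = (12, 15)
    band_level: float = 0.95
    max_lag: int = 12
    claims_scale: float = 1.0
    with_claims_stage: bool = False
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        sources = [
            self.synthetic is not None,
            self.claims_path is not None,
            self.series_dir is not None,
        ]
        if sum(sources) != 1:
            raise ConfigurationError(
                "exactly one data source (synthetic | claims | series) is required"
            )
        if self.claims_path is not None and self.registry_path is None:
            raise ConfigurationError("claims input requires a registry file")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sched = raw.pop("schedule", {})
        schedule = InterventionSchedule(**sched) if sched else InterventionSchedule()
        syn = raw.pop("synthetic", None)
        synthetic = None
        if syn is not None:
            syn.pop("schedule", None)
            synthetic = SyntheticConfig(
                schedule=schedule, seed=raw.get("seed", 0), **syn
            )
        for key in ("claims_path", "registry_path", "series_dir", "out_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("horizons", "outcomes", "groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(schedule=schedule, synthetic=synthetic, **raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (not output location)."""
        skip = {"out_dir", "verbosity"}
        payload = repr(
            sorted((k, v) for k, v in self.__dict__.items() if k not in skip)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    series: dict
    fits: dict
    effects: pd.DataFrame
    coefficients: pd.DataFrame
    growth: pd.DataFrame
    descriptives: pd.DataFrame
    manifest: dict


def _series_from_source(config: RunConfig) -> dict:
    if config.synthetic is not None:
        syn = config.synthetic
        if config.with_claims_stage:
            scaled = syn.scaled(config.claims_scale) if config.claims_scale != 1.0 else syn
            registry = make_default_registry()
            claims = generate_claims(scaled, registry)
            (config.out_dir / "data").mkdir(parents=True, exist_ok=True)
            claims.to_csv(config.out_dir / "data" / "claims.csv", index=False)
            registry_frame(registry).to_csv(config.out_dir / "data" / "registry.csv", index=False)
            cohort = select_cohort(claims, index_window=scaled.index_window)
            return aggregate_monthly(
                claims, cohort, registry,
                origin=scaled.schedule.origin, n_months=scaled.n_months,
            )
        return {
            (outcome, group): generate_monthly_series(syn, outcome, group)
            for outcome in config.outcomes
            for group in config.groups
            if (outcome, group) in syn.series
        }
    if config.claims_path is not None:
        claims = pd.read_csv(config.claims_path)
        registry_df = pd.read_csv(config.registry_path)
        from .synthetic import DrugEntry

        registry = [
            DrugEntry(
                code=r.code,
                group=r.group,
                unit_price_pre=r.unit_price_pre,
                unit_price_post=r.unit_price_post,
                who_ddd_units=None if pd.isna(r.who_ddd_units) else r.who_ddd_units,
                standard_daily_dose_units=(
                    None if pd.isna(r.standard_daily_dose_units) else r.standard_daily_dose_units
                ),
            )
            for r in registry_df.itertuples()
        ]
        cohort = select_cohort(claims)
        return aggregate_monthly(
            claims, cohort, registry,
            origin=config.schedule.origin, n_months=config.schedule.n_months,
        )
    series = {}
    for path in sorted(Path(config.series_dir).glob("*__*.csv")):
        outcome, group = path.stem.split("__", 1)
        series[(outcome, group)] = read_series(path, outcome, group)
    if not series:
        raise AggregationError(f"no series files found under {config.series_dir}")
    return series


def coefficient_table(fits: dict) -> pd.DataFrame:
    """Coefficient report in the style of a published segmented-ITS table."""
    rows = []
    for (outcome, group), fit in fits.items():
        marks = fit.markers()
        row = {"outcome": outcome, "group": group, "method": fit.method}
        for i, name in enumerate(fit.beta.index):
            row[f"b{i}"] = fit.beta.iloc[i]
            row[f"b{i}_mark"] = marks.iloc[i]
        row["ar1_rho"] = fit.rho if fit.rho is not None else ""
        row["dw"] = fit.dw
        row["dw_pvalue"] = fit.dw_pvalue if fit.dw_pvalue is not None else ""
        row["aic"] = fit.aic
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; deterministic given the config and seed."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    logging.getLogger("priceits").addHandler(handler)
    try:
        return _run(config, out)
    finally:
        logging.getLogger("priceits").removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> PipelineResult:
    X = build_design_matrix(config.schedule)
    X.reset_index().astype({"month": str}).to_csv(out / "design_matrix.csv", index=False)

    try:
        series = _series_from_source(config)
    except Exception as err:
        raise type(err)(f"[stage: data] {err}") from err

    (out / "series").mkdir(exist_ok=True)
    for (outcome, group), s in sorted(series.items()):
        write_series(s, out / "series" / f"{outcome}__{group}.csv")

    sched = config.schedule
    year_starts = pd.period_range(sched.origin, sched.origin + sched.n_months - 1, freq="M")
    periods = []
    start = sched.origin
    idx = 0
    while start <= year_starts[-1]:
        end = min(start + 11, year_starts[-1])
        periods.append((str(start.year), str(start), str(end)))
        start = start + 12
        idx += 1
    descriptives = descriptive_summary(series, periods)
    descriptives.to_csv(out / "descriptive_summary.csv", index=False)

    fits = {}
    effect_rows = []
    for (outcome, group), s in sorted(series.items()):
        try:
            ols = fit_ols(s, X)
            ar1 = fit_ar1_ml(s, X)
            dw_p = dw_pvalue(ols.dw, X, seed=config.seed)
            fit = select_model(ols, ar1, dw_p)
            fit.white_noise = white_noise_check(fit.resid, config.max_lag)
        except Exception as err:
            raise type(err)(f"[stage: fit {outcome}/{group}] {err}") from err
        fits[(outcome, group)] = fit
        try:
            summaries = percent_effect(fit, X, horizons=config.horizons, level=config.band_level)
        except Exception as err:
            logger.warning("effects undefined for %s/%s: %s", outcome, group, err)
            continue
        band = forecast_band(fit, X, level=config.band_level)
        cf = counterfactual_series(fit, X)
        pd.concat([cf, band[["lower", "upper"]]], axis=1).reset_index().astype(
            {"month": str}
        ).to_csv(out / "series" / f"forecast__{outcome}__{group}.csv", index=False)
        for es in summaries:
            effect_rows.append(
                {
                    "outcome": outcome,
                    "group": group,
                    "horizon_months": es.horizon_months,
                    "cumulative_percent": es.cumulative_percent,
                    "endpoint_percent": es.endpoint_percent,
                    "monthly_average_percent": es.monthly_average_percent,
                    "cumulative_absolute": es.cumulative_absolute,
                    "endpoint_absolute": es.endpoint_absolute,
                    "band_lower": es.band_lower,
                    "band_upper": es.band_upper,
                }
            )

    coefficients = coefficient_table(fits)
    coefficients.to_csv(out / "coefficients.csv", index=False)
    effects = pd.DataFrame(effect_rows)
    effects.to_csv(out / "effects.csv", index=False)

    if config.synthetic is not None:
        incidents = generate_procedure_incidents(config.synthetic)
        incidents.to_csv(out / "procedure_incidents.csv", index=False)
        rates = _observed_rates(incidents, config.synthetic)
    else:
        from .reference import complication_rate_table

        rates = complication_rate_table()
    growth = annual_growth(rates)
    growth.to_csv(out / "growth.csv", index=False)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package": {"priceits": _pkg_version, "numpy": np.__version__, "pandas": pd.__version__},
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*.csv")
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        series=series,
        fits=fits,
        effects=effects,
        coefficients=coefficients,
        growth=growth,
        descriptives=descriptives,
        manifest=manifest,
    )


def _observed_rates(incidents: pd.DataFrame, syn: SyntheticConfig) -> pd.DataFrame:
    """Category x period mean monthly episodes per 1000 from simulated counts."""
    inc = incidents.copy()
    months = pd.PeriodIndex(inc["month"], freq="M")
    origin = syn.schedule.origin
    inc["period_idx"] = [( (m - origin).n) // syn.complication_period_months for m in months]
    n_periods = max(len(v) for v in syn.complication_rates.values())
    inc["period_idx"] = inc["period_idx"].clip(upper=n_periods - 1)
    per1000 = inc.assign(rate=inc["count"] / syn.n_patients * 1000.0)
    table = per1000.pivot_table(index="category", columns="period_idx", values="rate", aggfunc="mean")
    table.columns = [f"period_{i + 1}" for i in table.columns]
    return table


REQUIRED_CLAIMS_COLUMNS = CLAIMS_COLUMNS
REQUIRED_REGISTRY_COLUMNS = [
    "code",
    "group",
    "unit_price_pre",
    "unit_price_post",
    "who_ddd_units",
    "standard_daily_dose_units",
]


def validate_inputs(paths: dict) -> dict:
    """Schema-check delimited inputs; returns per-file error lists and row counts.

    ``paths`` maps kind ("claims" | "registry" | "series") to a file path.
    Unreadable files raise immediately with the path in the message.
    """
    report: dict[str, dict] = {}
    for kind, path in paths.items():
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as err:
            raise OSError(f"cannot read {kind} file {path}: {err}") from err
        errors: list[str] = []
        if kind == "claims":
            missing = [c for c in REQUIRED_CLAIMS_COLUMNS if c not in df.columns]
            for col in missing:
                errors.append(f"missing required column: {col}")
            if not missing:
                dates = pd.to_datetime(df["service_date"], format="%Y-%m-%d", errors="coerce")
                nbad = int(dates.isna().sum())
                if nbad:
                    errors.append(f"{nbad} unparseable service_date value(s)")
                bad_setting = sorted(set(df["setting"]) - {"outpatient", "inpatient"})
                if bad_setting:
                    errors.append(f"invalid setting values: {bad_setting}")
                bad_ins = sorted(set(df["insurance"]) - {"NHI", "MedAid"})
                if bad_ins:
                    errors.append(f"invalid insurance values: {bad_ins}")
                over = int((df["copayment"] > df["cost"]).sum())
                if over:
                    errors.append(f"{over} row(s) with copayment > cost")
                neg = int((df["quantity"] < 0).sum() + (df["cost"] < 0).sum())
                if neg:
                    errors.append(f"{neg} negative quantity/cost value(s)")
        elif kind == "registry":
            missing = [c for c in REQUIRED_REGISTRY_COLUMNS if c not in df.columns]
            for col in missing:
                errors.append(f"missing required column: {col}")
            if not missing:
                bad_group = sorted(set(df["group"]) - {"reduced", "constant"})
                if bad_group:
                    errors.append(f"invalid group values: {bad_group}")
                nodose = df["who_ddd_units"].isna() & df["standard_daily_dose_units"].isna()
                if nodose.any():
                    errors.append(
                        f"{int(nodose.sum())} drug(s) without DDD or standard daily dose"
                    )
                if (df[["unit_price_pre", "unit_price_post"]] <= 0).any().any():
                    errors.append("non-positive unit price(s)")
        elif kind == "series":
            missing = [c for c in ("year", "month", "value") if c not in df.columns]
            for col in missing:
                errors.append(f"missing required column: {col}")
        else:
            errors.append(f"unknown input kind: {kind}")
        report[kind] = {"path": str(path), "rows": len(df), "errors": errors}
    return report
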