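"""Counterfactual forecasts and policy-effect summaries.

The counterfactual ("had the price cut not happened") sets the SPS level and
trend columns to zero in the design and re-evaluates the fitted mean; the
with-policy prediction uses the full design. Percent effects compare the two
model predictions (not the noisy observations) over the post-policy window,
which matches the forecast-band construction and is robust to residual noise;
an observed-vs-counterfactual variant is available via ``use_observed``.

Complication growth rates follow the published-table convention: percent
growth is rounded half away from zero to an integer and the absolute change
to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitResult

__all__ = [
    "EffectError",
    "EffectSummary",
    "counterfactual_series",
    "percent_effect",
    "forecast_band",
    "annual_growth",
    "round_half_away",
]

SPS_COLUMNS = ("sps", "time_after_sps")


class EffectError(ValueError):
    pass


def _design_pair(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Full and counterfactual design arrays (with intercept prepended)."""
    Xcf = X.copy()
    for col in SPS_COLUMNS:
        if col not in Xcf.columns:
            raise EffectError(f"design matrix lacks required column {col!r}")
        Xcf[col] = 0
    ones = np.ones(len(X))
    full = np.column_stack([ones, X.to_numpy(dtype=float)])
    cf = np.column_stack([ones, Xcf.to_numpy(dtype=float)])
    return full, cf, X.index


def counterfactual_series(fit: FitResult, X: pd.DataFrame) -> pd.DataFrame:
    """With-policy and counterfactual mean predictions per month."""
    full, cf, idx = _design_pair(X)
    b = fit.beta.to_numpy()
    return pd.DataFrame(
        {"with_policy": full @ b, "counterfactual": cf @ b}, index=idx
    )


@dataclass
class EffectSummary:
    """Policy effect at one horizon, as percent of the counterfactual.

    ``cumulative_percent`` always refers to the first 12 post-policy months
    (the headline "in a year" figure); ``endpoint_percent`` to the stated
    horizon month; ``monthly_average_percent`` is the arithmetic mean of the
    per-month percent differences over months 1..horizon.
    """

    outcome: str
    group: str
    horizon_months: int
    cumulative_percent: float
    endpoint_percent: float
    monthly_average_percent: float
    cumulative_absolute: float
    endpoint_absolute: float
    band_lower: float
    band_upper: float


def _delta_ratio_se(a: np.ndarray, bvec: np.ndarray, beta: np.ndarray, V: np.ndarray) -> float:
    """SE of 100*(a'beta)/(b'beta) by the delta method."""
    num = float(a @ beta)
    den = float(bvec @ beta)
    grad = 100.0 * (a * den - bvec * num) / den**2
    return float(np.sqrt(grad @ V @ grad))


def percent_effect(
    fit: FitResult,
    X: pd.DataFrame,
    horizons=(12, 15),
    level: float = 0.95,
    use_observed: bool = False,
    observed=None,
) -> list[EffectSummary]:
    """Percent policy effects at the given post-policy horizons.

    For horizon h (months after the policy start, inclusive of the start
    month): cumulative = 100*(sum y_hat - sum y_cf)/sum y_cf over months
    1..12; endpoint = the same ratio at month h alone; monthly average = mean
    of per-month percent differences over months 1..h. The 95% band is a
    delta-method interval on the endpoint percent.
    """
    full, cf, _ = _design_pair(X)
    b = fit.beta.to_numpy()
    V = fit.cov_beta.to_numpy()
    sps = X["sps"].to_numpy()
    if not sps.any():
        raise EffectError("design has no post-policy months")
    start = int(np.argmax(sps > 0))
    n_post = len(X) - start
    y_hat = full @ b
    if use_observed:
        if observed is None:
            raise EffectError("use_observed=True requires the observed series")
        y_hat = np.asarray(observed, dtype=float)
    y_cf = cf @ b
    if np.any(y_cf[start:] <= 0):
        raise EffectError("counterfactual prediction is not positive over the post window")

    out = []
    z = stats.norm.ppf(0.5 + level / 2)
    cum_h = min(12, n_post)
    a_cum = full[start : start + cum_h].sum(axis=0) - cf[start : start + cum_h].sum(axis=0)
    b_cum = cf[start : start + cum_h].sum(axis=0)
    cum_pct = 100.0 * (y_hat[start : start + cum_h].sum() - y_cf[start : start + cum_h].sum()) / y_cf[start : start + cum_h].sum()
    cum_abs = float(y_hat[start : start + cum_h].sum() - y_cf[start : start + cum_h].sum())
    for h in horizons:
        if h > n_post:
            raise EffectError(f"horizon {h} exceeds the {n_post}-month post window")
        i = start + h - 1
        end_pct = 100.0 * (y_hat[i] - y_cf[i]) / y_cf[i]
        monthly = 100.0 * (y_hat[start : start + h] - y_cf[start : start + h]) / y_cf[start : start + h]
        a_end = full[i] - cf[i]
        se_end = _delta_ratio_se(a_end, cf[i], b, V)
        out.append(
            EffectSummary(
                outcome=getattr(fit, "outcome", ""),
                group=getattr(fit, "group", ""),
                horizon_months=h,
                cumulative_percent=float(cum_pct),
                endpoint_percent=float(end_pct),
                monthly_average_percent=float(monthly.mean()),
                cumulative_absolute=cum_abs,
                endpoint_absolute=float(y_hat[i] - y_cf[i]),
                band_lower=float(end_pct - z * se_end),
                band_upper=float(end_pct + z * se_end),
            )
        )
    return out


def forecast_band(fit: FitResult, X: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Pointwise band for the counterfactual *mean* trajectory.

    band_t = yhat_cf,t +/- z * se(x_cf,t' beta_hat), with the coefficient
    covariance taken from the fit (the AR(1) observed-information covariance
    for AR(1) fits, the classical OLS covariance otherwise).
    """
    if not 0 <= level < 1:
        raise EffectError(f"coverage level must be in [0, 1), got {level}")
    _, cf, idx = _design_pair(X)
    b = fit.beta.to_numpy()
    V = fit.cov_beta.to_numpy()
    mean = cf @ b
    se = np.sqrt(np.einsum("ij,jk,ik->i", cf, V, cf))
    z = stats.norm.ppf(0.5 + level / 2) if level > 0 else 0.0
    return pd.DataFrame(
        {"counterfactual": mean, "lower": mean - z * se, "upper": mean + z * se},
        index=idx,
    )


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round to ``decimals`` places with ties going away from zero."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def annual_growth(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-period growth of complication-procedure rates.

    ``rates`` has one row per category and one column per ordered period,
    holding monthly episodes per 1000 patients. Returns one row per adjacent
    period transition with the absolute change (2 decimals) and percent
    growth (integer, half away from zero), both relative to the earlier
    period.
    """
    if rates.shape[1] < 2:
        raise EffectError("need at least two periods per category")
    periods = list(rates.columns)
    rows = []
    for cat, r in rates.iterrows():
        for j in range(1, len(periods)):
            earlier, later = float(r.iloc[j - 1]), float(r.iloc[j])
            if earlier <= 0:
                raise EffectError(
                    f"growth undefined for {cat!r} {periods[j-1]}->{periods[j]}: "
                    f"earlier rate is {earlier}"
                )
            change = Decimal(repr(later)) - Decimal(repr(earlier))
            pct = change / Decimal(repr(earlier)) * 100
            rows.append(
                {
                    "category": cat,
                    "from_period": periods[j - 1],
                    "to_period": periods[j],
                    "rate_from": earlier,
                    "rate_to": later,
                    "change": float(change.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)),
                    "growth_pct": int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP)),
                }
            )
    return pd.DataFrame(rows)
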