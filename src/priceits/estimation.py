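"""Fitting the segmented model: OLS and exact AR(1) maximum likelihood.

Two candidate error models are fitted to every monthly series:

* ordinary least squares (independent Gaussian errors), and
* a regression with strictly stationary AR(1) errors
  ``e_t = rho * e_{t-1} + u_t``, ``u_t ~ N(0, sigma_u^2)``, estimated by exact
  Gaussian maximum likelihood (the likelihood of the full joint normal with
  Toeplitz correlation ``rho^|i-j|``, evaluated through the Prais-Winsten
  transform and profiled over ``rho``).

The final model is the one with the smaller AIC, with
``AIC = 2k - 2 logL`` counting every free parameter (7 regression
coefficients plus ``sigma^2``, plus ``rho`` for the AR(1) fit: k = 8 or 9).
The Durbin-Watson statistic, a Monte-Carlo DW p-value and residual ACF/PACF
white-noise checks are reported as diagnostics.

Sign convention: positive ``rho`` means positive serial correlation (some
legacy software reports the negated value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson as _sm_dw
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

from .design import DESIGN_COLUMNS

__all__ = [
    "EstimationError",
    "FitResult",
    "WhiteNoiseReport",
    "SegmentSummary",
    "fit_ols",
    "fit_ar1_ml",
    "durbin_watson",
    "dw_pvalue",
    "select_model",
    "white_noise_check",
    "segment_slopes",
    "significance_marker",
]

logger = logging.getLogger(__name__)

#: Table-style significance markers: # p<0.1, * p<0.05, dagger p<0.01, section p<0.001.
_MARKERS = ((0.001, "§"), (0.01, "†"), (0.05, "*"), (0.1, "#"))


class EstimationError(RuntimeError):
    pass


def significance_marker(p: float) -> str:
    for cut, mark in _MARKERS:
        if p < cut:
            return mark
    return ""


def _prepare(y, X) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Coerce inputs to arrays; prepend the intercept column."""
    if hasattr(y, "values_array"):
        yv = y.values_array()
    elif isinstance(y, pd.Series):
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = list(DESIGN_COLUMNS[: Xv.shape[1]])
    if np.isnan(yv).any():
        raise EstimationError(
            "missing outcome values inside the fit window; the elapsed-time "
            "counters are calendar-defined, so months cannot be dropped"
        )
    if len(yv) != Xv.shape[0]:
        raise EstimationError(f"y has {len(yv)} rows but X has {Xv.shape[0]}")
    Xc = np.column_stack([np.ones(len(yv)), Xv])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the dependent columns via QR pivoting on the correlation scale
        _, R = np.linalg.qr(Xc)
        bad = [
            (["const"] + names)[j]
            for j in range(Xc.shape[1])
            if abs(R[j, j]) < 1e-8 * abs(R[0, 0])
        ]
        raise EstimationError(f"singular design matrix; dependent columns: {bad}")
    return yv, Xc, ["const"] + names


@dataclass
class FitResult:
    """Estimates for one outcome series under one error model.

    ``beta`` holds (b0..b6) = (intercept, time, OPIP level, OPIP trend,
    SPS level, SPS trend, February); ``sigma2`` is the innovation variance
    (ML, denominator n); ``aic = 2k - 2 loglik`` with k = :attr:`n_params`.
    """

    method: str  # "OLS" or "AR1"
    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    sigma2: float
    loglik: float
    aic: float
    dw: float
    nobs: int
    cov_beta: pd.DataFrame
    rho: float | None = None
    rho_se: float | None = None
    resid: np.ndarray | None = None
    fitted: np.ndarray | None = None
    endog: np.ndarray | None = None
    exog: np.ndarray | None = None
    boundary_warning: bool = False
    dw_pvalue: float | None = None

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1 + (0 if self.rho is None else 1)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """t-based intervals; df = n - (regression params + AR params)."""
        df = self.nobs - len(self.beta) - (0 if self.rho is None else 1)
        q = stats.t.ppf(0.5 + level / 2, df)
        return pd.DataFrame(
            {"lower": self.beta - q * self.se, "upper": self.beta + q * self.se}
        )

    def markers(self) -> pd.Series:
        return self.pvalues.map(significance_marker)


def fit_ols(y, X) -> FitResult:
    """Ordinary least squares with classical covariance and Gaussian loglik."""
    yv, Xc, names = _prepare(y, X)
    res = sm.OLS(yv, Xc).fit()
    n = len(yv)
    resid = res.resid
    sigma2 = float(resid @ resid) / n  # ML variance
    loglik = float(res.llf)
    return FitResult(
        method="OLS",
        beta=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        sigma2=sigma2,
        loglik=loglik,
        aic=2 * (len(names) + 1) - 2 * loglik,
        dw=durbin_watson(resid),
        nobs=n,
        cov_beta=pd.DataFrame(res.cov_params(), index=names, columns=names),
        resid=resid,
        fitted=np.asarray(res.fittedvalues),
        endog=yv,
        exog=Xc,
    )


def _pw_transform(a: np.ndarray, rho: float) -> np.ndarray:
    """Prais-Winsten whitening rows: first row scaled by sqrt(1-rho^2)."""
    out = np.empty_like(a, dtype=float)
    out[0] = np.sqrt(1.0 - rho * rho) * a[0]
    out[1:] = a[1:] - rho * a[:-1]
    return out


def ar1_loglik(beta: np.ndarray, rho: float, sigma2: float, yv, Xc) -> float:
    """Exact stationary-AR(1) Gaussian log-likelihood at given parameters."""
    n = len(yv)
    e = yv - Xc @ beta
    et = _pw_transform(e, rho)
    ssr = float(et @ et)
    return (
        -0.5 * n * np.log(2 * np.pi * sigma2)
        + 0.5 * np.log1p(-rho * rho)
        - ssr / (2 * sigma2)
    )


def _profile_fit(rho: float, yv, Xc):
    """GLS beta and concentrated loglik for a fixed rho."""
    yt = _pw_transform(yv, rho)
    Xt = _pw_transform(Xc, rho)
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    et = yt - Xt @ beta
    ssr = float(et @ et)
    n = len(yv)
    sigma2 = ssr / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * np.log1p(-rho * rho)
    return beta, sigma2, ll, Xt


_RHO_BOUND = 0.999


def fit_ar1_ml(y, X) -> FitResult:
    """Exact ML for the regression with stationary AR(1) errors.

    The likelihood is concentrated over (beta, sigma^2) and maximised over
    rho on (-1, 1) by a coarse grid plus bounded 1-D refinement. Standard
    errors come from the observed information (numerical Hessian over
    (beta, rho, log sigma^2)) at the optimum; p-values are two-sided normal.
    """
    yv, Xc, names = _prepare(y, X)
    n = len(yv)
    if n < 10:
        raise EstimationError(f"AR(1) ML needs n >= 10 observations, got {n}")

    grid = np.linspace(-0.95, 0.95, 39)
    lls = np.array([_profile_fit(r, yv, Xc)[2] for r in grid])
    r0 = grid[int(np.argmax(lls))]
    res = optimize.minimize_scalar(
        lambda r: -_profile_fit(r, yv, Xc)[2],
        bounds=(max(-_RHO_BOUND, r0 - 0.1), min(_RHO_BOUND, r0 + 0.1)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:  # pragma: no cover - bounded brent rarely fails
        raise EstimationError(f"AR(1) profile optimisation failed: {res.message}")
    rho = float(res.x)
    boundary = abs(rho) > 0.99
    if boundary:
        logger.warning("AR(1) rho estimate %.4f is near the stationarity boundary", rho)
    beta, sigma2, ll, Xt = _profile_fit(rho, yv, Xc)

    # observed information at the optimum, parameterised (beta, rho, log sigma2)
    def negll(theta):
        b = theta[:-2]
        r = np.tanh(theta[-2])  # keep |rho|<1 along finite-difference steps
        s2 = np.exp(theta[-1])
        return -ar1_loglik(b, r, s2, yv, Xc)

    theta_hat = np.concatenate([beta, [np.arctanh(np.clip(rho, -0.9999, 0.9999)), np.log(sigma2)]])
    p = len(beta)
    # degrees-of-freedom-corrected innovation variance in the coefficient
    # covariance (SSE/(n - p) rather than the ML /n), the convention of the
    # classic autoregression procedures this estimator mirrors
    dof_scale = n / (n - p)
    cov_beta_arr = None
    try:
        H = approx_hess1(theta_hat, negll)
        cov_theta = np.linalg.inv(H)
        diag = np.diag(cov_theta)
        if (diag[:p] > 0).all():
            cov_beta_arr = cov_theta[:p, :p] * dof_scale
            # delta method back from arctanh(rho)
            rho_se = float(np.sqrt(max(diag[-2], 0.0)) * (1 - rho * rho))
    except np.linalg.LinAlgError:
        pass
    if cov_beta_arr is None:
        # near-degenerate likelihoods (e.g. almost noise-free series) make the
        # finite-difference Hessian unreliable; fall back to the GLS covariance
        # at the fitted rho, which the Hessian block approximates anyway
        logger.warning("observed information ill-conditioned; using GLS covariance")
        cov_beta_arr = sigma2 * dof_scale * np.linalg.inv(Xt.T @ Xt)
        rho_se = float(np.sqrt((1 - rho * rho) / n))
    se_beta = np.sqrt(np.diag(cov_beta_arr))
    z = beta / se_beta
    pvals = 2 * stats.norm.sf(np.abs(z))
    resid = yv - Xc @ beta

    return FitResult(
        method="AR1",
        beta=pd.Series(beta, index=names),
        se=pd.Series(se_beta, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=sigma2,
        loglik=ll,
        aic=2 * (len(names) + 2) - 2 * ll,
        dw=durbin_watson(resid),
        nobs=n,
        cov_beta=pd.DataFrame(cov_beta_arr, index=names, columns=names),
        rho=rho,
        rho_se=rho_se,
        resid=resid,
        fitted=Xc @ beta,
        endog=yv,
        exog=Xc,
        boundary_warning=boundary,
    )


def durbin_watson(residuals) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2 (near 2 under independence)."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise EstimationError("Durbin-Watson needs at least 3 residuals")
    if not np.any(e):
        raise EstimationError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_dw(e))


def dw_pvalue(statistic: float, X, n_sim: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo one-sided DW p-value for positive serial correlation.

    Simulates i.i.d. Gaussian errors, projects them through the same design
    (residual-maker matrix), and returns the fraction of simulated DW values
    at or below the observed one. Invariant to residual scaling because DW is
    scale-free.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    Xc = np.column_stack([np.ones(Xv.shape[0]), Xv])
    n = Xc.shape[0]
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n_sim, n))
    coef, _, _, _ = np.linalg.lstsq(Xc, E.T, rcond=None)
    R = E.T - Xc @ coef  # columns are simulated residual vectors
    d = np.diff(R, axis=0)
    dws = (d * d).sum(axis=0) / (R * R).sum(axis=0)
    return float(np.mean(dws <= statistic))


def select_model(ols: FitResult, ar1: FitResult, dw_p: float | None = None) -> FitResult:
    """Pick the minimum-AIC fit; ties go to OLS (fewer parameters).

    The Durbin-Watson p-value of the OLS fit, when supplied, is recorded on
    the selected result as a diagnostic.
    """
    if ols.method != "OLS" or ar1.method != "AR1":
        raise EstimationError("select_model expects (OLS fit, AR1 fit)")
    if ols.nobs != ar1.nobs or not np.allclose(ols.endog, ar1.endog) or not np.allclose(ols.exog, ar1.exog):
        raise EstimationError("fits were not computed on identical (y, X)")
    chosen = ols if ols.aic <= ar1.aic else ar1
    chosen.dw_pvalue = dw_p if dw_p is not None else ols.dw_pvalue
    return chosen


@dataclass
class WhiteNoiseReport:
    passed: bool
    acf: np.ndarray  # lags 1..max_lag
    pacf: np.ndarray
    bound: float

    def __bool__(self) -> bool:  # allows `if white_noise_check(...)`
        return self.passed


def white_noise_check(residuals, max_lag: int = 12) -> WhiteNoiseReport:
    """Residual white-noise screen from sample ACF/PACF.

    Passes iff every autocorrelation at lags 1..max_lag lies inside the
    large-sample +/- 1.96/sqrt(n) band.
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if max_lag >= n / 2:
        raise EstimationError(f"max_lag {max_lag} must be < n/2 = {n / 2}")
    r = _sm_acf(e, nlags=max_lag, fft=False)[1:]
    pr = _sm_pacf(e, nlags=max_lag, method="ywm")[1:]
    bound = 1.96 / np.sqrt(n)
    return WhiteNoiseReport(passed=bool(np.all(np.abs(r) < bound)), acf=r, pacf=pr, bound=bound)


@dataclass
class SegmentSummary:
    """Per-segment slopes and level shifts implied by the coefficients."""

    baseline_slope: float
    post_opip_slope: float
    post_sps_slope: float
    baseline_level: float
    opip_level_change: float
    sps_level_change: float


def segment_slopes(fit) -> SegmentSummary:
    """Derive segment slopes/levels from a fit or a raw (b0..b6) vector.

    baseline slope = b1; post-OPIP slope = b1+b3; post-SPS slope = b1+b3+b5;
    level shifts are b2 (OPIP) and b4 (SPS).
    """
    if isinstance(fit, FitResult):
        b = fit.beta.to_numpy()
    else:
        b = np.asarray(fit, dtype=float)
    if len(b) < 6:
        raise EstimationError("need at least coefficients b0..b5")
    return SegmentSummary(
        baseline_slope=float(b[1]),
        post_opip_slope=float(b[1] + b[3]),
        post_sps_slope=float(b[1] + b[3] + b[5]),
        baseline_level=float(b[0]),
        opip_level_change=float(b[2]),
        sps_level_change=float(b[4]),
    )
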