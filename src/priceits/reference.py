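"""Published reference estimates for the Korean Single Price System study.

The original national-claims evaluation of the April 2012 Korean drug price
cut (the "Single Price System", SPS) reported segmented-regression
coefficients for fifteen outcome x price-group series and monthly
complication-procedure rates per 1000 diabetic outpatients across four
12-month periods. Those printed numbers are reproduced here as inputs for
worked examples and cross-checks: slope combinations and growth rates are
pure arithmetic on them. The underlying claims data are confidential and are
not shipped or required.

Coefficient order: (b0 baseline level, b1 baseline trend, b2 OPIP level,
b3 OPIP trend, b4 SPS level, b5 SPS trend, b6 February). ``rho`` is the
reported AR(1) coefficient (None for OLS fits); ``dw`` the Durbin-Watson
statistic. Units: costs in billion KRW, DDDs in millions, patients in
persons; per-patient outcomes in KRW and DDDs.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "REFERENCE_FITS",
    "COMPLICATION_RATES",
    "COMPLICATION_PERIODS",
    "reference_beta",
    "complication_rate_table",
]

#: outcome id -> group -> dict(beta=(b0..b6), rho, dw, method)
REFERENCE_FITS: dict[str, dict[str, dict]] = {
    "cost_total": {
        "overall": {
            "beta": (29.982, 0.295, -0.984, -0.136, -4.384, 0.192, -2.643),
            "rho": 0.282, "dw": 1.98, "method": "AR1",
        },
        "reduced": {
            "beta": (23.738, 0.065, 1.357, -0.185, -4.809, -0.023, -1.858),
            "rho": 0.277, "dw": 2.06, "method": "AR1",
        },
        "constant": {
            "beta": (6.240, 0.229, -2.264, 0.049, 0.384, 0.211, -0.856),
            "rho": -0.080, "dw": 1.80, "method": "AR1",
        },
    },
    "ddd_total": {
        "overall": {
            "beta": (79.447, 0.463, -0.556, -0.023, -1.058, -0.114, -6.344),
            "rho": 0.338, "dw": 2.12, "method": "AR1",
        },
        "reduced": {
            "beta": (70.638, 0.161, 1.321, -0.119, -1.442, -0.340, -5.002),
            "rho": 0.333, "dw": 2.14, "method": "AR1",
        },
        "constant": {
            "beta": (8.794, 0.301, -1.792, 0.094, 0.426, 0.220, -1.370),
            "rho": None, "dw": 1.99, "method": "OLS",
        },
    },
    "n_patients": {
        "overall": {
            "beta": (1408058, 11758, -47643, 1698, 17535, -2504, -89533),
            "rho": None, "dw": 1.95, "method": "OLS",
        },
        "reduced": {
            "beta": (1129486, 4909, -6604, 532, 7296, -7523, -64306),
            "rho": None, "dw": 2.07, "method": "OLS",
        },
        "constant": {
            "beta": (278489, 6820, -39690, 1207, 8751, 4989, -26186),
            "rho": -0.168, "dw": 1.79, "method": "AR1",
        },
    },
    "cost_per_patient": {
        "overall": {
            "beta": (43492, 160, -2149, -163, -3380, 107, -1063),
            "rho": None, "dw": 1.86, "method": "OLS",
        },
        "reduced": {
            "beta": (20992, -30, 1123, -145, -3670, 81, -550),
            "rho": None, "dw": 1.96, "method": "OLS",
        },
        "constant": {
            "beta": (22455, 183, -2800, -27, 2334, 3, -499),
            "rho": -0.485, "dw": 2.12, "method": "AR1",
        },
    },
    "ddd_per_patient": {
        "overall": {
            "beta": (94.160, 0.095, 0.317, -0.083, -1.564, -0.010, -2.610),
            "rho": 0.224, "dw": 2.12, "method": "AR1",
        },
        "reduced": {
            "beta": (62.535, -0.120, 1.330, -0.090, -1.416, 0.056, -1.384),
            "rho": 0.135, "dw": 2.04, "method": "AR1",
        },
        "constant": {
            "beta": (31.594, 0.215, -0.934, -0.0004, 0.005, -0.068, -1.123),
            "rho": None, "dw": 2.08, "method": "OLS",
        },
    },
}

#: Four ordered 12-month reporting periods for complication rates.
COMPLICATION_PERIODS = ["2009", "2010", "2011", "2012"]

#: category -> monthly procedure episodes per 1000 cohort patients, per period.
COMPLICATION_RATES: dict[str, list[float]] = {
    "retinopathy": [0.27, 0.29, 0.30, 0.30],
    "cataract": [1.98, 2.08, 2.19, 2.23],
    "nephropathy": [0.47, 0.67, 0.74, 0.75],
    "cardiovascular": [2.49, 2.84, 2.90, 2.76],
    "foot_lesions": [0.40, 0.53, 0.62, 0.68],
}


def reference_beta(outcome: str, group: str) -> tuple[float, ...]:
    return REFERENCE_FITS[outcome][group]["beta"]


def complication_rate_table() -> pd.DataFrame:
    """Rates as a category x period DataFrame, ready for ``annual_growth``."""
    return pd.DataFrame.from_dict(
        COMPLICATION_RATES, orient="index", columns=COMPLICATION_PERIODS
    )
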