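#!/usr/bin/env python
"""Select the diabetic outpatient cohort and build monthly outcome series.

Reads the claims and registry written by 01_simulate.py, applies the cohort
rules (age >= 20, outpatient E11/E14 claim during Jan 2010 - Dec 2012,
excluded institution types dropped), aggregates to the five outcomes per
price group, and writes a descriptive per-period summary table.
"""

from pathlib import Path

import pandas as pd

import priceits as p

root = Path(__file__).resolve().parents[1] / "results"
data = root / "data"

claims = pd.read_csv(data / "claims.csv")
reg_df = pd.read_csv(data / "registry.csv")
registry = [
    p.DrugEntry(
        code=r.code, group=r.group,
        unit_price_pre=r.unit_price_pre, unit_price_post=r.unit_price_post,
        who_ddd_units=None if pd.isna(r.who_ddd_units) else r.who_ddd_units,
        standard_daily_dose_units=(
            None if pd.isna(r.standard_daily_dose_units) else r.standard_daily_dose_units
        ),
    )
    for r in reg_df.itertuples()
]

report = p.validate_inputs({"claims": data / "claims.csv", "registry": data / "registry.csv"})
for kind, entry in report.items():
    status = "ok" if not entry["errors"] else f"errors: {entry['errors']}"
    print(f"validate {kind}: {entry['rows']} rows, {status}")

cohort = p.select_cohort(claims)
series = p.aggregate_monthly(claims, cohort, registry, origin="2009-01", n_months=54)

out = root / "series_from_claims"
out.mkdir(parents=True, exist_ok=True)
for (outcome, group), s in sorted(series.items()):
    p.write_series(s, out / f"{outcome}__{group}.csv")

periods = [(str(y), f"{y}-01", f"{y}-12") for y in (2009, 2010, 2011, 2012)]
summary = p.descriptive_summary(series, periods)
summary.to_csv(root / "descriptive_summary.csv", index=False)

print(f"cohort: {len(cohort)} patients "
      f"({claims.patient_id.nunique() - len(cohort)} filtered out)")
cost = summary[(summary.outcome == "cost_total") & (summary.group == "overall")]
print("overall monthly antidiabetic cost (KRW), mean +/- SD by year:")
for _, r in cost.iterrows():
    print(f"  {r.period}: {r['mean']:.3e} +/- {r.sd:.2e}")
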