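#!/usr/bin/env python
"""Generate the synthetic study data.

Writes, under results/data/: a drug registry (97 ingredient codes, 32 with a
reduced price), patient-level claims for a downscaled cohort (1/2000 of the
four-million-patient study population, keeping per-patient structure), and
the fifteen aggregate monthly outcome series at the published study
conditions. Everything is reproducible from the single seed below.
"""

from pathlib import Path

import priceits as p

SEED = 1
SCALE = 0.0005  # 2000-patient pool for the claims-level dataset

out = Path(__file__).resolve().parents[1] / "results" / "data"
out.mkdir(parents=True, exist_ok=True)

full = p.SyntheticConfig(seed=SEED)
registry = p.make_default_registry()
p.registry_frame(registry).to_csv(out / "registry.csv", index=False)

claims = p.generate_claims(full.scaled(SCALE), registry)
claims.to_csv(out / "claims.csv", index=False)

series_dir = out / "series"
series_dir.mkdir(exist_ok=True)
for outcome, group in sorted(full.series):
    s = p.generate_monthly_series(full, outcome, group)
    p.write_series(s, series_dir / f"{outcome}__{group}.csv")

n_drug = int(claims.drug_code.notna().sum())
print(f"registry: {len(registry)} drugs ({sum(e.group == 'reduced' for e in registry)} reduced price)")
print(f"claims: {len(claims)} rows, {claims.patient_id.nunique()} patients, "
      f"{n_drug} antidiabetic prescriptions")
print(f"aggregate series: {len(full.series)} outcome x group files under {series_dir}")
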