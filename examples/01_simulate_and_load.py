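"""Simulate a cohort, write it to the CSV dialects, reload, apply exclusions.

The generator mirrors the structure of a subarachnoid-hemorrhage monitoring
cohort: five vital-sign channels on a regular grid with missing segments,
baseline grades, ~30% DCI prevalence, a handful of records excluded for an
early event (before post-bleed day 3) or for missing every candidate feature.
"""

import tempfile
from pathlib import Path

import dcipred as dp

cs, ms = dp.preset("cohort-structure", seed=0)
cohort = dp.generate_cohort(cs, ms)
print(f"generated {len(cohort)} records, prevalence "
      f"{cohort.labels().mean():.2f}")

with tempfile.TemporaryDirectory() as tmp:
    ts_csv = Path(tmp) / "timeseries.csv"
    base_csv = Path(tmp) / "baseline.csv"
    dp.write_cohort(cohort, ts_csv, base_csv)
    reloaded = dp.load_cohort(ts_csv, "long-csv", baseline_path=base_csv)
    print(f"round-tripped {len(reloaded)} records through CSV")

kept, report = dp.apply_exclusions(cohort)
print("exclusion report:", report)
# n_remaining is the analysis cohort: records with an event before
# post-bleed day 3 or with no candidate feature at all are dropped.
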