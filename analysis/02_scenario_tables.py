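"""Current-scenario tables: filter the ensemble and aggregate yearly demand.

Keeps the replications representative of the program as observed today
(20-year mean participation 40-60%, FIT positivity 4.7-6.8%, surveillance
adherence 35-70%) and tabulates, per calendar year, the across-run mean and
95% interval of invitations, participation, FIT positives, colonoscopies
after a positive FIT, and surveillance colonoscopies.

Requires results/runs_yearly.csv from 01_run_ensemble.py.
"""

from pathlib import Path

import pandas as pd

from crcdemand.aggregation import (aggregate_runs, filter_scenario,
                                   runs_from_yearly_frame, yearly_series)
from crcdemand.runner import StudyConfig

out = Path("results")
study = StudyConfig.load()
runs = runs_from_yearly_frame(pd.read_csv(out / "runs_yearly.csv"),
                              pd.read_csv(out / "runs_summary.csv"))
kept = filter_scenario(runs, study.scenario)
print(f"current-scenario filter kept {len(kept)}/{len(runs)} runs")

agg = aggregate_runs(kept)
agg.to_csv(out / "results_yearly.csv", index=False)

index = yearly_series(agg, "colono_index_total").set_index("year")["mean"]
surv = yearly_series(agg, "surveillance").set_index("year")["mean"]
first, last = index.index.min(), index.index.max()
print(f"colonoscopies after a positive FIT: {index[first]:.0f} ({first}) -> "
      f"{index[last]:.0f} ({last}); yearly mean {index.mean():.0f}")
print(f"surveillance colonoscopies:          0 ({first}) -> "
      f"{surv[last]:.0f} ({last})")
print(f"overall demand {index[first] + surv[first]:.0f} -> "
      f"{index[last] + surv[last]:.0f}: "
      f"x{(index[last] + surv[last]) / (index[first] + surv[first]):.1f} "
      f"over the horizon")

for name, fields in (("participation_positivity_series.csv",
                      ("participants", "fit_positive")),
                     ("colonoscopy_series.csv",
                      ("colono_index_total", "surveillance", "overall"))):
    parts = []
    for f in fields:
        s = yearly_series(agg, f)
        s.insert(0, "field", f)
        parts.append(s)
    pd.concat(parts, ignore_index=True).to_csv(out / name, index=False)
print(f"wrote {out/'results_yearly.csv'} and trajectory series")
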