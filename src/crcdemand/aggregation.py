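"""Replication ensemble, the current-scenario run filter, and yearly tables.

A probabilistic sensitivity analysis run ensemble executes many replications
with independent random streams, each under its own parameter draw.  Runs are
summarized by their 20-year mean participation (participants/invited), mean
FIT positivity (positives/participants) and surveillance adherence; the
"current scenario" subgroup keeps runs whose three summaries fall inside
bounds representative of the program observed today (participation 40-60%,
positivity 4.7-6.8%, adherence 35-70%).

Aggregation reports, for every tallied field and year, the across-run mean
and a 95% interval (empirical 2.5th-97.5th percentiles by default, or a
normal CI of the mean), plus derived percentages computed from the summed
numerators and denominators (percentages of colonoscopy results attach to
first index exams; surveillance percentages to attended exams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Demography
from .engine import RunResult, run_simulation
from .parameters import PriorLibrary
from .surveillance import SurveillancePolicy

#: (field, percentage denominator field or None)
_PCT_DENOM = {
    "participants": "invited",
    "participants_successive": "participants",
    "fit_positive": "participants",
    "colono_index_first": "fit_positive",
    "index_negative": "colono_index_first",
    "index_low_risk": "colono_index_first",
    "index_intermediate_risk": "colono_index_first",
    "index_high_risk": "colono_index_first",
    "index_cancer": "colono_index_first",
    "surv_negative": "surveillance",
    "surv_low_risk": "surveillance",
    "surv_intermediate_high_risk": "surveillance",
    "surv_cancer": "surveillance",
}


@dataclass(frozen=True)
class ScenarioFilter:
    """Closed bounds on the three run-level summary statistics."""

    participation: tuple = (0.40, 0.60)
    positivity: tuple = (0.047, 0.068)
    adherence: tuple = (0.35, 0.70)

    def __post_init__(self):
        for name in ("participation", "positivity", "adherence"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds must satisfy lower < upper")

    def keeps(self, run: RunResult) -> bool:
        lo, hi = self.participation
        if not lo <= run.mean_participation <= hi:
            return False
        lo, hi = self.positivity
        if not lo <= run.mean_positivity <= hi:
            return False
        lo, hi = self.adherence
        return lo <= run.adherence <= hi


def scenario_filter_from_config(cfg: dict) -> ScenarioFilter:
    f = cfg.get("run", {}).get("filter", {})
    kw = {k: tuple(float(v) for v in f[k]) for k in
          ("participation", "positivity", "adherence") if k in f}
    return ScenarioFilter(**kw)


def run_ensemble(priors: PriorLibrary, demog: Demography, n_runs: int,
                 base_seed: int, horizon: int = 20,
                 policy: SurveillancePolicy | None = None,
                 progress: bool = False) -> list[RunResult]:
    """Run ``n_runs`` replications from independent child streams.

    Child streams are spawned from a single SeedSequence, so the ensemble is
    reproducible from ``base_seed`` and each run is independent of the
    others; results are keyed by run index.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_runs)
    out = []
    for i, child in enumerate(children):
        res = run_simulation(priors, demog, child, horizon=horizon, policy=policy)
        res.seed = i
        out.append(res)
        if progress and (i + 1) % 100 == 0:
            print(f"  run {i + 1}/{n_runs}", flush=True)
    return out


def filter_scenario(runs: list[RunResult],
                    filt: ScenarioFilter | None = None) -> list[RunResult]:
    """Keep runs whose summary statistics fall inside the (closed) bounds."""
    filt = filt or ScenarioFilter()
    return [r for r in runs if filt.keeps(r)]


def runs_summary_frame(runs: list[RunResult]) -> pd.DataFrame:
    """One row per run: summary parameters and 20-year totals."""
    rows = []
    for r in runs:
        rows.append({
            "run": r.seed,
            "mean_participation": r.mean_participation,
            "mean_positivity": r.mean_positivity,
            "adherence": r.adherence,
            "total_invited": int(r.yearly.invited.sum()),
            "total_participants": int(r.yearly.participants.sum()),
            "total_fit_positive": int(r.yearly.fit_positive.sum()),
            "total_index_colonoscopies": int(r.yearly.colono_index_total.sum()),
            "total_surveillance_colonoscopies": int(r.yearly.surveillance.sum()),
        })
    return pd.DataFrame(rows)


def runs_yearly_frame(runs: list[RunResult]) -> pd.DataFrame:
    """Long table with one row per (run, year) and all tally fields."""
    frames = []
    for r in runs:
        f = r.to_frame()
        f.insert(0, "run", r.seed)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def runs_from_yearly_frame(yearly: pd.DataFrame,
                           summary: pd.DataFrame) -> list[RunResult]:
    """Rebuild RunResult objects from the exported long/summary tables."""
    from .engine import Tallies

    adher = summary.set_index("run")["adherence"]
    out = []
    for run_id, grp in yearly.groupby("run", sort=True):
        grp = grp.sort_values("year")
        horizon = len(grp)
        tal = Tallies(horizon)
        tal.invited[:] = grp["invited"].to_numpy()
        tal.participants[:] = grp["participants"].to_numpy()
        tal.participants_successive[:] = grp["participants_successive"].to_numpy()
        tal.fit_positive[:] = grp["fit_positive"].to_numpy()
        tal.colono_index_first[:] = grp["colono_index_first"].to_numpy()
        tal.colono_index_total[:] = grp["colono_index_total"].to_numpy()
        tal.index_outcome[:] = grp[["index_negative", "index_low_risk",
                                    "index_intermediate_risk", "index_high_risk",
                                    "index_cancer"]].to_numpy()
        tal.surveillance[:] = grp["surveillance"].to_numpy()
        tal.surv_outcome[:] = grp[["surv_negative", "surv_low_risk",
                                   "surv_intermediate_high_risk",
                                   "surv_cancer"]].to_numpy()
        out.append(RunResult(seed=int(run_id), start_year=int(grp["year"].iloc[0]),
                             yearly=tal, adherence=float(adher.loc[run_id])))
    return out


def aggregate_runs(runs: list[RunResult], ci: str = "percentile") -> pd.DataFrame:
    """Across-run mean and 95% interval per (year, field), with derived %.

    ``ci="percentile"``: empirical 2.5th-97.5th percentiles across runs with
    linear interpolation; ``ci="mean"``: normal 95% CI of the across-run mean.
    Percentages divide the across-run mean numerator by the across-run mean
    of its denominator field.
    """
    if len(runs) < 2:
        raise ValueError("aggregation intervals require at least 2 runs")
    frames = [r.to_frame() for r in runs]
    years = frames[0]["year"].to_numpy()
    fields = [c for c in frames[0].columns if c != "year"]
    cube = np.stack([f[fields].to_numpy(dtype=float) for f in frames])
    mean = cube.mean(axis=0)
    if ci == "percentile":
        lo = np.percentile(cube, 2.5, axis=0)
        hi = np.percentile(cube, 97.5, axis=0)
    elif ci == "mean":
        se = cube.std(axis=0, ddof=1) / np.sqrt(cube.shape[0])
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    recs = []
    fidx = {f: j for j, f in enumerate(fields)}
    for j, f in enumerate(fields):
        denom_f = _PCT_DENOM.get(f)
        for i, y in enumerate(years):
            pct = np.nan
            if denom_f is not None:
                d = mean[i, fidx[denom_f]]
                pct = 100.0 * mean[i, j] / d if d > 0 else np.nan
            recs.append({
                "year": int(y), "field": f, "mean": mean[i, j],
                "lo95": lo[i, j], "hi95": hi[i, j], "pct": pct,
            })
    return pd.DataFrame(recs)


def yearly_series(agg: pd.DataFrame, field: str) -> pd.DataFrame:
    """Extract one field's (year, mean, lo95, hi95, pct) series."""
    return (agg[agg["field"] == field]
            .drop(columns="field").reset_index(drop=True))
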