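"""Regression meta-model of colonoscopy demand over the run ensemble.

The ensemble's per-run, per-year summaries (participation, positivity, both
in percentage points; run-constant adherence in percentage points; year
index t = year - start) are regressed on the yearly colonoscopy counts with
ordinary least squares:

    count ~ participation + positivity + adherence + t
            + participation:t + positivity:t + adherence:t
            + positivity:participation

One model is fitted per outcome (colonoscopies after a positive FIT,
surveillance colonoscopies, overall).  Because predictors are in percentage
points, a coefficient reads directly as "extra colonoscopies per +1%", and
the marginal effect of a parameter at year t (and, through the
positivity-by-participation interaction, at a conditioning value of the
other parameter) is an affine function of the fitted coefficients, with a
delta-method standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .engine import RunResult

log = logging.getLogger(__name__)

OUTCOMES = ("index", "surveillance", "overall")

_TERMS = ("const", "participation", "positivity", "adherence", "t",
          "participation_t", "positivity_t", "adherence_t",
          "positivity_participation")


def build_design(runs: list[RunResult], outcome: str = "index") -> pd.DataFrame:
    """One row per (run, year): predictors in % units plus the outcome count.

    Years with no invited persons or no participants have undefined
    participation/positivity and are dropped with a warning.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    rows = []
    dropped = 0
    for r in runs:
        y = r.yearly
        for t in range(y.horizon):
            inv, par = y.invited[t], y.participants[t]
            if inv == 0 or par == 0:
                dropped += 1
                continue
            if outcome == "index":
                count = y.colono_index_total[t]
            elif outcome == "surveillance":
                count = y.surveillance[t]
            else:
                count = y.colono_index_total[t] + y.surveillance[t]
            rows.append({
                "run": r.seed, "t": t,
                "participation": 100.0 * y.participants[t] / inv,
                "positivity": 100.0 * y.fit_positive[t] / par,
                "adherence": 100.0 * r.adherence,
                "count": int(count),
            })
    if dropped:
        log.warning("build_design: dropped %d run-years with zero denominator", dropped)
    return pd.DataFrame(rows)


@dataclass
class SensitivityModel:
    """Fitted OLS coefficients of the demand meta-regression."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    resid_var: float
    nobs: int
    rsquared: float

    def coef(self, term: str) -> float:
        return float(self.params[term])


def _design_matrix(rows: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({
        "const": 1.0,
        "participation": rows["participation"],
        "positivity": rows["positivity"],
        "adherence": rows["adherence"],
        "t": rows["t"].astype(float),
        "participation_t": rows["participation"] * rows["t"],
        "positivity_t": rows["positivity"] * rows["t"],
        "adherence_t": rows["adherence"] * rows["t"],
        "positivity_participation": rows["positivity"] * rows["participation"],
    })
    return X


def fit_sensitivity_model(rows: pd.DataFrame, outcome: str = "index") -> SensitivityModel:
    """Ordinary least squares on the meta-design; errors on rank deficiency."""
    X = _design_matrix(rows)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        cols = list(X.columns)
        for j in range(X.shape[1]):
            sub = X.drop(columns=cols[j]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(cols[j])
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    res = sm.OLS(rows["count"].to_numpy(dtype=float), X).fit()
    return SensitivityModel(
        outcome=outcome,
        params=res.params, bse=res.bse,
        cov=res.cov_params(),
        resid_var=float(res.mse_resid), nobs=int(res.nobs),
        rsquared=float(res.rsquared),
    )


def fit_all_outcomes(runs: list[RunResult]) -> dict[str, SensitivityModel]:
    return {
        o: fit_sensitivity_model(build_design(runs, o), o) for o in OUTCOMES
    }


def marginal_effect(model: SensitivityModel, parameter: str, t: float,
                    participation: float | None = None,
                    positivity: float | None = None) -> tuple[float, float]:
    """Extra colonoscopies per +1 percentage point of a parameter.

    effect(participation) = b_part + b_part:t * t + b_pos:part * positivity
    effect(positivity)    = b_pos  + b_pos:t  * t + b_pos:part * participation
    effect(adherence)     = b_adh  + b_adh:t  * t

    Conditioning values are in percentage points.  Returns (effect, se) with
    the delta-method (here: exact, the effect is linear in the coefficients)
    standard error.
    """
    g = pd.Series(0.0, index=model.params.index)
    if parameter == "participation":
        if positivity is None:
            raise ValueError("participation effect requires a positivity value")
        g["participation"] = 1.0
        g["participation_t"] = t
        g["positivity_participation"] = positivity
    elif parameter == "positivity":
        if participation is None:
            raise ValueError("positivity effect requires a participation value")
        g["positivity"] = 1.0
        g["positivity_t"] = t
        g["positivity_participation"] = participation
    elif parameter == "adherence":
        g["adherence"] = 1.0
        g["adherence_t"] = t
    else:
        raise ValueError(f"unknown parameter {parameter!r}")
    effect = float(g @ model.params)
    se = float(np.sqrt(g @ model.cov.to_numpy() @ g))
    return effect, se


def effects_grid(models: dict[str, SensitivityModel], t_values=range(20),
                 participation_values=(30, 40, 50, 60, 70),
                 positivity_values=(2, 3, 4, 5, 6)) -> pd.DataFrame:
    """The marginal-effect surfaces: one row per (outcome, parameter, year,
    conditioning value)."""
    recs = []
    for oname, model in models.items():
        for t in t_values:
            for p in positivity_values:
                e, se = marginal_effect(model, "participation", t, positivity=p)
                recs.append({"outcome": oname, "parameter": "participation",
                             "t": t, "conditioning": p, "effect": e, "se": se})
            for p in participation_values:
                e, se = marginal_effect(model, "positivity", t, participation=p)
                recs.append({"outcome": oname, "parameter": "positivity",
                             "t": t, "conditioning": p, "effect": e, "se": se})
            e, se = marginal_effect(model, "adherence", t)
            recs.append({"outcome": oname, "parameter": "adherence",
                         "t": t, "conditioning": np.nan, "effect": e, "se": se})
    return pd.DataFrame(recs)
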