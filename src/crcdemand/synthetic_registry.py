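"""Synthetic screening-registry records and parameter re-estimation.

The source program's person-level round 1-2 registry is not public.  This
module generates a synthetic stand-in with known parameters - age/gender-
stratified Bernoulli outcomes along the screening chain (invitation ->
exclusion -> opportunistic -> participation -> FIT result -> colonoscopy
refusal -> result category) for two rounds, with round-2 participation
conditioned on round-1 behavior - and re-estimates every chain probability
from the records.  This closes the calibration loop: estimates recovered
from a registry generated under a known ParameterSet can be fed back into
the simulator as point-mass priors.

Estimation is by stratified conditional proportions with exact
(Clopper-Pearson) 95% binomial intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import (AGE_GROUPS, GENDERS, RESULT_CATEGORIES, ParameterSet)

_REGISTRY_COLUMNS = (
    "person_id", "round", "gender", "age_group", "excluded", "opportunistic",
    "invited", "participated", "fit_positive", "colonoscopy_done", "outcome",
)


def _chain_round(n, g, a, params: ParameterSet, rng, prev_participated=None,
                 screen_number=None):
    """One round of Bernoulli draws for n persons of stratum (g, a).

    Returns a dict of outcome arrays; nested flags are False/NA downstream of
    a failed stage.  ``prev_participated`` None marks a first invitation.
    """
    if prev_participated is None:
        p_excl = params.exclusion_initial[g, a]
    else:
        p_excl = params.exclusion_successive
    excluded = rng.random(n) < p_excl
    opportunistic = ~excluded & (rng.random(n) < params.opportunistic[g, a])
    invited = ~excluded & ~opportunistic

    if prev_participated is None:
        p_part = np.full(n, params.participation_initial[g, a])
    else:
        p_part = np.where(prev_participated,
                          params.participation_successive_prev_participant,
                          params.participation_successive_prev_nonparticipant)
    participated = invited & (rng.random(n) < p_part)

    if screen_number is None:
        first_screen = np.ones(n, dtype=bool)
    else:
        first_screen = np.asarray(screen_number) == 1
    p_pos = np.where(first_screen, params.positivity_initial[g, a],
                     params.positivity_successive)
    fit_positive = participated & (rng.random(n) < p_pos)

    colonoscopy_done = fit_positive & (rng.random(n) >= params.refusal[g, a])

    u = rng.random(n)
    cum_i = np.cumsum(params.result_dist_initial)
    cum_s = np.cumsum(params.result_dist_successive)
    cat = np.where(first_screen,
                   np.minimum(np.searchsorted(cum_i, u, side="right"), 4),
                   np.minimum(np.searchsorted(cum_s, u, side="right"), 4))
    return {
        "excluded": excluded, "opportunistic": opportunistic, "invited": invited,
        "participated": participated, "fit_positive": fit_positive,
        "colonoscopy_done": colonoscopy_done, "outcome_code": cat,
    }


def generate_registry(true_params: ParameterSet, n_per_stratum: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Two rounds of synthetic person-level records, n_per_stratum per stratum.

    Round 2 re-invites everyone except those who exited round 1 (exclusion,
    detected cancer, or surveillance entry after intermediate/high-risk
    adenomas) and opportunistic screeners deferred two rounds.  Round-2
    participation is conditioned on round-1 participation; a participant's
    second FIT uses successive-screen positivity while a round-1
    non-participant's first FIT still uses initial positivity.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    frames = []
    pid0 = 0
    for g, gender in enumerate(GENDERS):
        for a, age_group in enumerate(AGE_GROUPS):
            n = n_per_stratum
            ids = np.arange(pid0, pid0 + n)
            pid0 += n
            r1 = _chain_round(n, g, a, true_params, rng)
            frames.append(_round_frame(ids, 1, gender, age_group, r1))

            # round-2 eligibility
            cat = r1["outcome_code"]
            exit_r1 = r1["excluded"] | (
                r1["colonoscopy_done"] & np.isin(cat, (2, 3, 4))
            )
            recent = rng.random(n) < true_params.opportunistic_recent_fraction
            deferred = r1["opportunistic"] & recent  # +4 y: skips round 2
            elig = ~exit_r1 & ~deferred
            n2 = int(elig.sum())
            if n2 == 0:
                continue
            prev_part = r1["participated"][elig]
            screen_number = np.where(prev_part, 2, 1)
            r2 = _chain_round(n2, g, a, true_params, rng,
                              prev_participated=prev_part,
                              screen_number=screen_number)
            frames.append(_round_frame(ids[elig], 2, gender, age_group, r2))
    return pd.concat(frames, ignore_index=True)


def _round_frame(ids, rnd, gender, age_group, r) -> pd.DataFrame:
    outcome = np.where(
        r["colonoscopy_done"],
        np.asarray(RESULT_CATEGORIES, dtype=object)[r["outcome_code"]],
        None,
    )
    return pd.DataFrame({
        "person_id": ids,
        "round": rnd,
        "gender": gender,
        "age_group": age_group,
        "excluded": r["excluded"],
        "opportunistic": r["opportunistic"],
        "invited": r["invited"],
        "participated": r["participated"],
        "fit_positive": np.where(r["participated"], r["fit_positive"], None),
        "colonoscopy_done": np.where(r["fit_positive"] & r["participated"],
                                     r["colonoscopy_done"], None),
        "outcome": outcome,
    })


def _ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson binomial interval."""
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _prop_row(parameter, gender, age_group, k, n):
    if n == 0:
        return {"parameter": parameter, "gender": gender, "age_group": age_group,
                "estimate": np.nan, "lo95": np.nan, "hi95": np.nan,
                "successes": 0, "trials": 0}
    lo, hi = _ci(int(k), int(n))
    return {"parameter": parameter, "gender": gender, "age_group": age_group,
            "estimate": k / n, "lo95": lo, "hi95": hi,
            "successes": int(k), "trials": int(n)}


def estimate_parameters(records: pd.DataFrame) -> pd.DataFrame:
    """Conditional-proportion estimates of every chain probability.

    Returns one row per (parameter, stratum) - or per parameter with
    gender/age_group "all" for unstratified fields - with exact 95% binomial
    intervals.  Denominators follow the chain nesting: opportunistic
    screeners are removed from the participation denominator.
    """
    if len(records) == 0:
        raise ValueError("empty registry")
    df = records
    r1 = df[df["round"] == 1]
    r2 = df[df["round"] == 2]
    rows = []

    for gender in GENDERS:
        for age_group in AGE_GROUPS:
            s1 = r1[(r1["gender"] == gender) & (r1["age_group"] == age_group)]
            rows.append(_prop_row("exclusion_initial", gender, age_group,
                                  s1["excluded"].sum(), len(s1)))
            not_excl = s1[~s1["excluded"]]
            rows.append(_prop_row("opportunistic", gender, age_group,
                                  not_excl["opportunistic"].sum(), len(not_excl)))
            inv = s1[s1["invited"]]
            rows.append(_prop_row("participation_initial", gender, age_group,
                                  inv["participated"].sum(), len(inv)))
            par = inv[inv["participated"]]
            rows.append(_prop_row("positivity_initial", gender, age_group,
                                  (par["fit_positive"] == True).sum(), len(par)))  # noqa: E712
            pos = df[(df["gender"] == gender) & (df["age_group"] == age_group)
                     & (df["fit_positive"] == True)]  # noqa: E712
            rows.append(_prop_row("refusal", gender, age_group,
                                  (pos["colonoscopy_done"] == False).sum(), len(pos)))  # noqa: E712

    rows.append(_prop_row("exclusion_successive", "all", "all",
                          r2["excluded"].sum(), len(r2)))

    # round-2 participation conditioned on round-1 behavior
    r1_part = r1.set_index("person_id")["participated"]
    r2i = r2[r2["invited"]]
    prev = r1_part.reindex(r2i["person_id"]).to_numpy(dtype=bool)
    rows.append(_prop_row("participation_successive_prev_participant", "all", "all",
                          r2i["participated"].to_numpy()[prev].sum(), prev.sum()))
    rows.append(_prop_row("participation_successive_prev_nonparticipant", "all", "all",
                          r2i["participated"].to_numpy()[~prev].sum(), (~prev).sum()))

    # successive positivity: second screens (round-2 participants who also
    # participated in round 1)
    r2p = r2i[r2i["participated"]]
    prev_p = r1_part.reindex(r2p["person_id"]).to_numpy(dtype=bool)
    rows.append(_prop_row("positivity_successive", "all", "all",
                          (r2p["fit_positive"] == True).to_numpy()[prev_p].sum(),  # noqa: E712
                          prev_p.sum()))

    # result-category shares among done colonoscopies, by screen number
    done = df[df["colonoscopy_done"] == True]  # noqa: E712
    first_mask = ((done["round"] == 1).to_numpy()
                  | ~r1_part.reindex(done["person_id"]).to_numpy(dtype=bool))
    for label, sub in (("result_dist_initial", done[first_mask]),
                       ("result_dist_successive", done[~first_mask])):
        n = len(sub)
        for cat in RESULT_CATEGORIES:
            rows.append(_prop_row(f"{label}.{cat}", "all", "all",
                                  (sub["outcome"] == cat).sum(), n))
    return pd.DataFrame(rows)


def estimates_as_point_parameters(est: pd.DataFrame,
                                  template: ParameterSet) -> ParameterSet:
    """Build a ParameterSet from registry estimates (point values), keeping
    the template's structural fields (second-look, surveillance, adherence)."""
    import copy
    ps = copy.deepcopy(template)

    def stratified(parameter):
        arr = np.zeros((2, 4))
        for g, gender in enumerate(GENDERS):
            for a, age_group in enumerate(AGE_GROUPS):
                v = est[(est["parameter"] == parameter)
                        & (est["gender"] == gender_name(g))
                        & (est["age_group"] == age_group)]["estimate"]
                arr[g, a] = float(v.iloc[0])
        return arr

    def gender_name(g):
        return GENDERS[g]

    def scalar(parameter):
        v = est[est["parameter"] == parameter]["estimate"]
        return float(v.iloc[0])

    ps.exclusion_initial = stratified("exclusion_initial")
    ps.opportunistic = stratified("opportunistic")
    ps.participation_initial = stratified("participation_initial")
    ps.positivity_initial = stratified("positivity_initial")
    ps.refusal = stratified("refusal")
    ps.exclusion_successive = scalar("exclusion_successive")
    ps.participation_successive_prev_participant = scalar(
        "participation_successive_prev_participant")
    ps.participation_successive_prev_nonparticipant = scalar(
        "participation_successive_prev_nonparticipant")
    ps.positivity_successive = scalar("positivity_successive")
    for field_name, cats in (("result_dist_initial", RESULT_CATEGORIES),
                             ("result_dist_successive", RESULT_CATEGORIES)):
        shares = np.array([scalar(f"{field_name}.{c}") for c in cats])
        setattr(ps, field_name, shares / shares.sum())
    return ps
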