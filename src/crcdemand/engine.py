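"""Discrete-event core of the screening microsimulation.

Events are processed in yearly batches over a continuous time axis: within a
simulation year every pending surveillance exam and every pending invitation
is resolved, in vectorized form, for all persons at once.  Because every
follow-on event lands at least one year downstream (re-invitations at +2/+4/
+10 years, surveillance exams at +1/+3/+5 years) and yearly tallies only
depend on the calendar year of each event, batching by year is equivalent to
a strict time-ordered event queue for every reported quantity.

The screening chain at an invitation is: exclusion -> opportunistic
screening -> participation (FIT pick-up and return collapsed into one
probability) -> FIT result -> colonoscopy refusal -> index colonoscopy with
possible second-look repeats -> result category -> routing (re-invitation,
surveillance entry, or exit on invasive cancer).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import surveillance as surv
from .cohort import (EXCLUDED, EXITED, ROUTINE, Demography, Population,
                     annual_entrants, init_population)
from .parameters import (ParameterSet, PriorLibrary, sample_parameters, stratum_of)
from .surveillance import SurveillancePolicy, process_surveillance_year

# index colonoscopy outcome codes
NEGATIVE, LOW, INTERMEDIATE, HIGH, CANCER = 0, 1, 2, 3, 4

#: tallied per-year fields, in export order
TALLY_FIELDS = (
    "invited", "participants", "participants_successive", "fit_positive",
    "colono_index_first", "colono_index_total",
    "index_negative", "index_low_risk", "index_intermediate_risk",
    "index_high_risk", "index_cancer",
    "surveillance",
    "surv_negative", "surv_low_risk", "surv_intermediate_high_risk", "surv_cancer",
)


class Tallies:
    """Per-calendar-year event counts for one run."""

    def __init__(self, horizon: int):
        self.horizon = horizon
        self.invited = np.zeros(horizon, dtype=np.int64)
        self.participants = np.zeros(horizon, dtype=np.int64)
        self.participants_successive = np.zeros(horizon, dtype=np.int64)
        self.fit_positive = np.zeros(horizon, dtype=np.int64)
        self.colono_index_first = np.zeros(horizon, dtype=np.int64)
        self.colono_index_total = np.zeros(horizon, dtype=np.int64)
        self.index_outcome = np.zeros((horizon, 5), dtype=np.int64)
        self.surveillance = np.zeros(horizon, dtype=np.int64)
        self.surv_outcome = np.zeros((horizon, 4), dtype=np.int64)
        # oldest age at which any surveillance exam was performed (invariant:
        # strictly below the policy age cap)
        self.max_surv_exam_age = -np.inf

    def to_frame(self, start_year: int) -> pd.DataFrame:
        d = {
            "year": np.arange(start_year, start_year + self.horizon),
            "invited": self.invited,
            "participants": self.participants,
            "participants_successive": self.participants_successive,
            "fit_positive": self.fit_positive,
            "colono_index_first": self.colono_index_first,
            "colono_index_total": self.colono_index_total,
            "index_negative": self.index_outcome[:, NEGATIVE],
            "index_low_risk": self.index_outcome[:, LOW],
            "index_intermediate_risk": self.index_outcome[:, INTERMEDIATE],
            "index_high_risk": self.index_outcome[:, HIGH],
            "index_cancer": self.index_outcome[:, CANCER],
            "surveillance": self.surveillance,
            "surv_negative": self.surv_outcome[:, 0],
            "surv_low_risk": self.surv_outcome[:, 1],
            "surv_intermediate_high_risk": self.surv_outcome[:, 2],
            "surv_cancer": self.surv_outcome[:, 3],
        }
        df = pd.DataFrame(d)
        df["overall"] = df["colono_index_total"] + df["surveillance"]
        return df


def process_invitation(pop: Population, idx: np.ndarray, t: np.ndarray,
                       params: ParameterSet, rng: np.random.Generator,
                       tallies: Tallies) -> tuple[np.ndarray, np.ndarray]:
    """Resolve exclusion and opportunistic screening for an invitation batch.

    Returns the indices (and invitation times) of persons effectively
    invited, who proceed to the participation decision; tallies them.  Excluded persons leave the target
    population permanently; opportunistic screeners are deferred +4 years
    (colonoscopy within the last 3 years) or +2 years (3-5 years ago).
    """
    if idx.size == 0:
        return idx, np.asarray(t, dtype=float)
    t = np.asarray(t, dtype=float)
    age = pop.age0[idx] + t
    if np.any((age < 50.0 - 1e-9) | (age >= 70.0)):
        raise ValueError("routine invitation outside ages [50, 70)")
    g, a = stratum_of(pop.gender[idx], age)
    p_excl = np.where(
        pop.ever_screen_invited[idx],
        params.exclusion_successive,
        params.exclusion_initial[g, a],
    )
    u = rng.random(idx.size)
    excl = u < p_excl
    pop.status[idx[excl]] = EXCLUDED
    pop.next_invite[idx[excl]] = np.inf

    rest = ~excl
    p_opp = params.opportunistic[g, a]
    opp = rest & (rng.random(idx.size) < p_opp)
    recent = rng.random(idx.size) < params.opportunistic_recent_fraction
    iv = np.where(recent,
                  params.reinvite_intervals["opportunistic_le_3y"],
                  params.reinvite_intervals["opportunistic_3_5y"])
    pop.next_invite[idx[opp]] = (t + iv)[opp]

    keep = rest & ~opp
    invited = idx[keep]
    t_inv = t[keep]
    yr = np.floor(t_inv).astype(np.intp)
    np.add.at(tallies.invited, yr, 1)
    return invited, t_inv


def draw_participation(pop: Population, idx: np.ndarray, t: np.ndarray,
                       params: ParameterSet, rng: np.random.Generator,
                       tallies: Tallies) -> tuple[np.ndarray, np.ndarray]:
    """Participation decision; returns indices and times of participants.

    First-time invitees use the stratified initial probability; re-invitees
    use the successive probability conditioned on previous-round behavior.
    Non-participants are re-invited after 2 years.
    """
    if idx.size == 0:
        return idx, np.asarray(t, dtype=float)
    age = pop.age0[idx] + t
    g, a = stratum_of(pop.gender[idx], age)
    p = np.where(
        pop.ever_screen_invited[idx],
        np.where(pop.prev_participant[idx],
                 params.participation_successive_prev_participant,
                 params.participation_successive_prev_nonparticipant),
        params.participation_initial[g, a],
    )
    pop.ever_screen_invited[idx] = True
    part = rng.random(idx.size) < p
    non = idx[~part]
    pop.prev_participant[non] = False
    pop.next_invite[non] = t[~part] + params.reinvite_intervals["non_participation"]

    pidx = idx[part]
    pop.prev_participant[pidx] = True
    t_part = t[part]
    yr = np.floor(t_part).astype(np.intp)
    np.add.at(tallies.participants, yr, 1)
    successive = pop.screen_count[pidx] > 0
    np.add.at(tallies.participants_successive, yr[successive], 1)
    return pidx, t_part


def draw_fit_result(pop: Population, idx: np.ndarray, t: np.ndarray,
                    params: ParameterSet, rng: np.random.Generator,
                    tallies: Tallies) -> tuple[np.ndarray, np.ndarray]:
    """FIT result for participants; returns indices/times of positive tests.

    Positivity is stratified for a person's first screen and a single
    successive-screen probability afterwards.  Negatives are re-invited after
    2 years; the screen count is incremented for everyone tested.
    """
    if idx.size == 0:
        return idx, np.asarray(t, dtype=float)
    age = pop.age0[idx] + t
    g, a = stratum_of(pop.gender[idx], age)
    p = np.where(pop.screen_count[idx] > 0,
                 params.positivity_successive,
                 params.positivity_initial[g, a])
    pos = rng.random(idx.size) < p
    pop.screen_count[idx] += 1
    neg = idx[~pos]
    pop.next_invite[neg] = t[~pos] + params.reinvite_intervals["negative_fit"]

    t_pos = t[pos]
    yr = np.floor(t_pos).astype(np.intp)
    np.add.at(tallies.fit_positive, yr, 1)
    return idx[pos], t_pos


def _second_looks(n: int, rate: float, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Number of second-look repeats per index exam.

    ``chain``: every exam (including a repeat) can indicate a further repeat
    with the same probability, so repeats are geometric with mean
    rate/(1-rate).  ``single``: at most one repeat (Bernoulli).
    """
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if rate <= 0:
        return np.zeros(n, dtype=np.int64)
    if mode == "single":
        return (rng.random(n) < rate).astype(np.int64)
    return rng.geometric(1.0 - rate, size=n) - 1


def perform_index_colonoscopy(pop: Population, idx: np.ndarray, t: np.ndarray,
                              params: ParameterSet, rng: np.random.Generator,
                              tallies: Tallies,
                              policy: SurveillancePolicy) -> None:
    """Colonoscopy after a positive FIT: refusal, exam, second-looks, routing.

    Refusers are re-invited after 2 years.  Attended exams tally one first
    colonoscopy plus second-look repeats (attributed to the same year, since
    they are indicated by and belong to the index exam's episode).  The
    result category uses the initial distribution for first screens and the
    successive one otherwise; routing: negative -> re-invite +10 y, low risk
    -> +2 y, intermediate/high -> surveillance, invasive cancer -> exit.
    """
    if idx.size == 0:
        return
    age = pop.age0[idx] + t
    g, a = stratum_of(pop.gender[idx], age)
    refuse = rng.random(idx.size) < params.refusal[g, a]
    ref = idx[refuse]
    pop.next_invite[ref] = t[refuse] + params.reinvite_intervals["refusal"]

    done = idx[~refuse]
    td = t[~refuse]
    if done.size == 0:
        return
    yr = np.floor(td).astype(np.intp)
    np.add.at(tallies.colono_index_first, yr, 1)
    extras = _second_looks(done.size, params.second_look_rate,
                           params.second_look_mode, rng)
    np.add.at(tallies.colono_index_total, yr, 1 + extras)

    first_screen = pop.screen_count[done] == 1
    u = rng.random(done.size)
    cum_i = np.cumsum(params.result_dist_initial)
    cum_s = np.cumsum(params.result_dist_successive)
    out_i = np.minimum(np.searchsorted(cum_i, u, side="right"), 4)
    out_s = np.minimum(np.searchsorted(cum_s, u, side="right"), 4)
    outcome = np.where(first_screen, out_i, out_s)
    np.add.at(tallies.index_outcome, (yr, outcome), 1)

    m = outcome == NEGATIVE
    pop.next_invite[done[m]] = td[m] + params.reinvite_intervals["negative_index_colonoscopy"]
    m = outcome == LOW
    pop.next_invite[done[m]] = td[m] + params.reinvite_intervals["low_risk_adenoma"]
    m = outcome == CANCER
    pop.status[done[m]] = EXITED
    pop.next_invite[done[m]] = np.inf
    m = (outcome == INTERMEDIATE) | (outcome == HIGH)
    surv.schedule_surveillance(pop, done[m], (outcome == HIGH)[m], td[m], policy)


def _process_invitation_year(pop: Population, params: ParameterSet,
                             policy: SurveillancePolicy, year_index: int,
                             rng: np.random.Generator, tallies: Tallies) -> None:
    sel = np.flatnonzero((pop.status == ROUTINE) & (pop.next_invite < year_index + 1))
    if sel.size == 0:
        return
    t = pop.next_invite[sel]
    pop.next_invite[sel] = np.inf
    # death before the invitation instant: silent exit
    dead = t >= pop.death[sel]
    pop.status[sel[dead]] = EXITED
    sel, t = sel[~dead], t[~dead]
    # ageing out of the target population (no further routine invitations)
    over = pop.age0[sel] + t >= 70.0
    pop.status[sel[over]] = EXITED
    sel, t = sel[~over], t[~over]
    if sel.size == 0:
        return
    invited, t_inv = process_invitation(pop, sel, t, params, rng, tallies)
    participants, t_par = draw_participation(pop, invited, t_inv, params, rng, tallies)
    positives, t_pos = draw_fit_result(pop, participants, t_par, params, rng, tallies)
    perform_index_colonoscopy(pop, positives, t_pos, params, rng, tallies, policy)


@dataclass
class RunResult:
    """One run's yearly tallies plus its run-level summary parameters."""

    seed: int
    start_year: int
    yearly: Tallies
    adherence: float
    params: ParameterSet | None = None
    final_status: dict = dc_field(default_factory=dict)
    total_entered: int = 0

    @property
    def mean_participation(self) -> float:
        inv = self.yearly.invited.sum()
        return float(self.yearly.participants.sum() / inv) if inv else np.nan

    @property
    def mean_positivity(self) -> float:
        par = self.yearly.participants.sum()
        return float(self.yearly.fit_positive.sum() / par) if par else np.nan

    def to_frame(self) -> pd.DataFrame:
        return self.yearly.to_frame(self.start_year)


def run_simulation(priors: PriorLibrary, demog: Demography, seed,
                   horizon: int = 20,
                   policy: SurveillancePolicy | None = None,
                   keep_params: bool = False) -> RunResult:
    """Execute one complete 20-year replication.

    Samples one ParameterSet from the priors, builds the initial cohort,
    feeds yearly entrant cohorts, and processes surveillance exams and
    invitations year by year.  Fully reproducible from the seed.
    """
    policy = policy or SurveillancePolicy()
    rng = np.random.default_rng(seed)
    params = sample_parameters(priors, rng)
    pop = init_population(demog, rng)
    tallies = Tallies(horizon)
    total_entered = len(pop)
    for y in range(horizon):
        year = demog.start_year + y
        if y >= 1:
            ent = annual_entrants(demog, year, rng, horizon=horizon)
            total_entered += len(ent)
            pop.append(ent)
        process_surveillance_year(pop, params, policy, y, rng, tallies)
        _process_invitation_year(pop, params, policy, y, rng, tallies)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return RunResult(
        seed=int(seed_int), start_year=demog.start_year, yearly=tallies,
        adherence=params.adherence_successive_surveillance,
        params=params if keep_params else None,
        final_status=pop.status_counts(), total_entered=total_entered,
    )
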