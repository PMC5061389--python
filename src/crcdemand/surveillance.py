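"""Post-polypectomy surveillance: scheduling, adherence, and routing.

Persons whose index colonoscopy finds intermediate- or high-risk adenomas
enter a guideline surveillance scheme: high risk is re-examined after 1 year,
intermediate risk after 3 years.  At each attended exam the outcome is drawn
from the surveillance result distribution and routed:

* intermediate/high-risk finding -> next exam in 3 years (negatives reset);
* low-risk finding               -> back to routine screening in 2 years;
* first consecutive negative     -> next exam in 3 years;
* second consecutive negative    -> next exam in 5 years;
* third consecutive negative     -> back to routine screening in 5 years;
* invasive cancer                -> exit from the model.

Adherence is 100% for the first exam of a surveillance episode and a
run-constant probability for successive exams.  A missed exam is by default
retried one year later (the person stays under surveillance; the exam is not
tallied); setting ``missed_exam="drop"`` makes non-adherence absorbing
instead.  No surveillance exam ever takes place at age 80 or over: exams that
would fall beyond the age cap (or beyond death) are not scheduled and the
person leaves the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import EXITED, ROUTINE, SURVEILLANCE, Population
from .parameters import ParameterSet

# surveillance outcome codes
S_NEG, S_LOW, S_IH, S_CANCER = 0, 1, 2, 3


@dataclass(frozen=True)
class SurveillancePolicy:
    """The transition table of the surveillance scheme (intervals in years)."""

    entry_interval_high: float = 1.0
    entry_interval_intermediate: float = 3.0
    finding_interval: float = 3.0           # after an intermediate/high finding
    negative_intervals: tuple = (3.0, 5.0)  # after the 1st, 2nd consecutive negative
    negatives_to_exit: int = 3              # nth consecutive negative returns to routine
    routine_return_after_negatives: float = 5.0
    routine_return_low_risk: float = 2.0
    age_cap: float = 80.0                   # no exam at or beyond this age
    missed_exam: str = "reschedule"         # "reschedule" | "drop"
    retry_interval: float = 1.0


def policy_from_config(cfg: dict) -> SurveillancePolicy:
    s = cfg.get("surveillance", {})
    kw = {}
    for key in ("entry_interval_high", "entry_interval_intermediate",
                "finding_interval", "routine_return_after_negatives",
                "routine_return_low_risk", "age_cap", "retry_interval"):
        if key in s:
            kw[key] = float(s[key])
    if "negative_intervals" in s:
        kw["negative_intervals"] = tuple(float(v) for v in s["negative_intervals"])
    if "negatives_to_exit" in s:
        kw["negatives_to_exit"] = int(s["negatives_to_exit"])
    if "missed_exam" in s:
        if s["missed_exam"] not in ("reschedule", "drop"):
            raise ValueError(f"surveillance.missed_exam: {s['missed_exam']!r}")
        kw["missed_exam"] = s["missed_exam"]
    return SurveillancePolicy(**kw)


def _cancel_if_unreachable(pop: Population, idx: np.ndarray, when: np.ndarray,
                           policy: SurveillancePolicy) -> np.ndarray:
    """Exit persons whose next exam would fall at age >= cap or after death;
    return the boolean mask of exams that remain scheduled."""
    ok = (pop.age0[idx] + when < policy.age_cap) & (when < pop.death[idx])
    bad = idx[~ok]
    pop.status[bad] = EXITED
    pop.surv_next[bad] = np.inf
    return ok


def schedule_surveillance(pop: Population, idx: np.ndarray, high_risk: np.ndarray,
                          now: np.ndarray, policy: SurveillancePolicy) -> None:
    """Enter persons into surveillance after an intermediate/high-risk finding.

    ``high_risk`` is a boolean mask aligned with ``idx``; ``now`` the exam
    times.  The first exam lands at +1 y (high) or +3 y (intermediate); if it
    would fall at age >= 80 or after death it is not scheduled and the person
    exits the model.
    """
    idx = np.asarray(idx)
    if idx.size == 0:
        return
    when = np.asarray(now) + np.where(
        high_risk, policy.entry_interval_high, policy.entry_interval_intermediate
    )
    pop.status[idx] = SURVEILLANCE
    pop.next_invite[idx] = np.inf
    pop.surv_consec_neg[idx] = 0
    pop.surv_exams[idx] = 0
    pop.surv_next[idx] = when
    # unreachable first exams (age cap or death) cancel the episode entirely
    _cancel_if_unreachable(pop, idx, when, policy)


def process_surveillance_year(pop: Population, params: ParameterSet,
                              policy: SurveillancePolicy, year_index: int,
                              rng: np.random.Generator, tallies) -> None:
    """Process all surveillance exams scheduled within one simulation year.

    Missed exams retried at sub-year intervals can come due again within the
    same year, so the pass repeats until no exam remains pending.
    """
    while True:
        sel = np.flatnonzero(
            (pop.status == SURVEILLANCE) & (pop.surv_next < year_index + 1)
        )
        if sel.size == 0:
            return
        _surveillance_pass(pop, params, policy, sel, rng, tallies)


def _surveillance_pass(pop: Population, params: ParameterSet,
                       policy: SurveillancePolicy, sel: np.ndarray,
                       rng: np.random.Generator, tallies) -> None:
    t = pop.surv_next[sel]
    # deaths before the exam cancel it silently
    dead = t >= pop.death[sel]
    pop.status[sel[dead]] = EXITED
    pop.surv_next[sel[dead]] = np.inf
    sel, t = sel[~dead], t[~dead]
    if sel.size == 0:
        return

    # adherence: 100% for the first exam of an episode, run-constant after
    first = pop.surv_exams[sel] == 0
    attend = first | (rng.random(sel.size) < params.adherence_successive_surveillance)

    missed = sel[~attend]
    if missed.size:
        tm = t[~attend]
        if policy.missed_exam == "reschedule":
            when = tm + policy.retry_interval
            pop.surv_next[missed] = when
            _cancel_if_unreachable(pop, missed, when, policy)
        else:  # absorbing non-adherence
            pop.status[missed] = EXITED
            pop.surv_next[missed] = np.inf

    sel, t = sel[attend], t[attend]
    if sel.size == 0:
        return
    yr = np.floor(t).astype(np.intp)
    np.add.at(tallies.surveillance, yr, 1)
    pop.surv_exams[sel] += 1
    tallies.max_surv_exam_age = max(tallies.max_surv_exam_age,
                                    float((pop.age0[sel] + t).max()))

    cum = np.cumsum(params.surveillance_result_dist)
    outcome = np.searchsorted(cum, rng.random(sel.size), side="right")
    outcome = np.minimum(outcome, 3)
    np.add.at(tallies.surv_outcome, (yr, outcome), 1)

    # cancer: exit the model
    m = outcome == S_CANCER
    pop.status[sel[m]] = EXITED
    pop.surv_next[sel[m]] = np.inf

    # low-risk finding: back to routine screening
    m = outcome == S_LOW
    back = sel[m]
    pop.status[back] = ROUTINE
    pop.surv_next[back] = np.inf
    pop.next_invite[back] = t[m] + policy.routine_return_low_risk

    # intermediate/high finding: next exam, negatives reset
    m = outcome == S_IH
    pop.surv_consec_neg[sel[m]] = 0
    nxt = sel[m]
    when = t[m] + policy.finding_interval
    pop.surv_next[nxt] = when
    _cancel_if_unreachable(pop, nxt, when, policy)

    # negative: escalate intervals; after the nth consecutive negative the
    # person returns to routine screening
    m = outcome == S_NEG
    neg = sel[m]
    if neg.size:
        pop.surv_consec_neg[neg] += 1
        k = pop.surv_consec_neg[neg]
        done = k >= policy.negatives_to_exit
        out = neg[done]
        pop.status[out] = ROUTINE
        pop.surv_next[out] = np.inf
        pop.next_invite[out] = t[m][done] + policy.routine_return_after_negatives
        cont = neg[~done]
        if cont.size:
            ivals = np.asarray(policy.negative_intervals)
            ki = np.minimum(k[~done], len(ivals)) - 1
            when = t[m][~done] + ivals[ki]
            pop.surv_next[cont] = when
            _cancel_if_unreachable(pop, cont, when, policy)
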