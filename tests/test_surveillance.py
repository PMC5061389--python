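import numpy as np
import pytest

from crcdemand.cohort import EXITED, ROUTINE, SURVEILLANCE, Population
from crcdemand.engine import Tallies
from crcdemand.surveillance import (SurveillancePolicy, S_NEG,
                                    process_surveillance_year,
                                    schedule_surveillance)

from test_engine import make_params


def enter(n=1, age=60.0, high=True, now=0.0, policy=None):
    pop = Population(n)
    pop.age0[:] = age
    schedule_surveillance(pop, np.arange(n), np.full(n, high),
                          np.full(n, float(now)), policy or SurveillancePolicy())
    return pop


def run_years(pop, params, policy, years=20, seed=0):
    rng = np.random.default_rng(seed)
    tal = Tallies(years)
    for y in range(years):
        process_surveillance_year(pop, params, policy, y, rng, tal)
    return tal


def hand_scheduler(entry_risk, outcomes, policy=None):
    """Independent table-driven walk-through of the surveillance scheme
    (pure bookkeeping, no engine code): returns (exam_times, routine_time)."""
    p = policy or SurveillancePolicy()
    t = (p.entry_interval_high if entry_risk == "high"
         else p.entry_interval_intermediate)
    exams, consec = [], 0
    for out in outcomes:
        exams.append(t)
        if out == "cancer":
            return exams, None
        if out == "low":
            return exams, t + p.routine_return_low_risk
        if out == "finding":
            consec = 0
            t += p.finding_interval
            continue
        consec += 1
        if consec >= p.negatives_to_exit:
            return exams, t + p.routine_return_after_negatives
        t += p.negative_intervals[min(consec, len(p.negative_intervals)) - 1]
    return exams, None


class TestScheduling:
    def test_high_risk_first_exam_after_one_year(self):
        pop = enter(high=True, now=2.25)
        assert pop.status[0] == SURVEILLANCE
        assert pop.surv_next[0] == 3.25
        assert np.isinf(pop.next_invite[0])

    def test_intermediate_first_exam_after_three_years(self):
        pop = enter(high=False, now=2.25)
        assert pop.surv_next[0] == 5.25

    def test_surveillance_continues_past_routine_exit_age(self):
        # high-risk finding at 69: the exam at 70 still happens
        pop = enter(age=69.0, high=True)
        assert pop.status[0] == SURVEILLANCE
        assert pop.surv_next[0] == 1.0

    def test_exam_beyond_age_cap_not_scheduled(self):
        # intermediate finding at 78: first exam would be at 81 -> exit
        pop = enter(age=78.0, high=False)
        assert pop.status[0] == EXITED
        assert np.isinf(pop.surv_next[0])


class TestWalkThrough:
    def test_all_negative_path_matches_hand_simulation(self):
        """High-risk entry at t=0, every finding negative, full adherence:
        exams at t = 1, 4, 9 and routine re-entry at t = 14."""
        exams, routine = hand_scheduler("high", ["neg"] * 5)
        assert exams == [1.0, 4.0, 9.0]
        assert routine == 14.0

        params = make_params(adherence_successive_surveillance=1.0)
        params.surveillance_result_dist = np.array([1.0, 0.0, 0.0, 0.0])
        pop = enter(high=True, age=55.0)
        tal = run_years(pop, params, SurveillancePolicy())
        exam_years = np.flatnonzero(tal.surveillance).tolist()
        assert exam_years == [1, 4, 9]
        assert tal.surveillance.sum() == 3
        assert pop.status[0] == ROUTINE
        assert pop.next_invite[0] == 14.0

    def test_intermediate_all_negative_path(self):
        exams, routine = hand_scheduler("intermediate", ["neg"] * 5)
        assert exams == [3.0, 6.0, 11.0] and routine == 16.0
        params = make_params(adherence_successive_surveillance=1.0)
        params.surveillance_result_dist = np.array([1.0, 0.0, 0.0, 0.0])
        pop = enter(high=False, age=55.0)
        tal = run_years(pop, params, SurveillancePolicy())
        assert np.flatnonzero(tal.surveillance).tolist() == [3, 6, 11]
        assert pop.next_invite[0] == 16.0

    def test_persistent_findings_keep_three_year_cycle(self):
        exams, _ = hand_scheduler("high", ["finding"] * 4)
        assert exams == [1.0, 4.0, 7.0, 10.0]
        params = make_params(adherence_successive_surveillance=1.0)
        params.surveillance_result_dist = np.array([0.0, 0.0, 1.0, 0.0])
        pop = enter(high=True, age=55.0)
        tal = run_years(pop, params, SurveillancePolicy(), years=11)
        assert np.flatnonzero(tal.surveillance).tolist() == [1, 4, 7, 10]
        assert pop.status[0] == SURVEILLANCE

    def test_low_risk_finding_returns_to_routine(self):
        params = make_params(adherence_successive_surveillance=1.0)
        params.surveillance_result_dist = np.array([0.0, 1.0, 0.0, 0.0])
        pop = enter(high=True, age=55.0)
        tal = run_years(pop, params, SurveillancePolicy(), years=5)
        assert tal.surveillance.sum() == 1
        assert pop.status[0] == ROUTINE
        assert pop.next_invite[0] == 3.0  # exam at 1 + 2-year routine return

    def test_cancer_at_surveillance_exits_model(self):
        params = make_params()
        params.surveillance_result_dist = np.array([0.0, 0.0, 0.0, 1.0])
        pop = enter(high=True, age=55.0)
        tal = run_years(pop, params, SurveillancePolicy(), years=5)
        assert tal.surveillance.sum() == 1
        assert pop.status[0] == EXITED


class TestAdherence:
    def test_zero_adherence_gives_exactly_one_exam_per_entry(self):
        """The first exam of an episode is always attended; with adherence 0
        no further exam ever is, whatever the retry policy."""
        n = 2_000
        params = make_params(adherence_successive_surveillance=0.0)
        params.surveillance_result_dist = np.array([1.0, 0.0, 0.0, 0.0])
        pop = enter(n=n, high=True, age=55.0)
        tal = run_years(pop, params, SurveillancePolicy())
        assert tal.surveillance.sum() == n

    def test_exam_count_monotone_in_adherence(self):
        counts = []
        # entrants near the age cap: low adherence delays exams past it
        for adh in (0.3, 0.7):
            params = make_params(adherence_successive_surveillance=adh)
            pop = enter(n=5_000, high=True, age=70.0)
            tal = run_years(pop, params, SurveillancePolicy(), seed=4)
            counts.append(tal.surveillance.sum())
        assert counts[1] > counts[0]

    def test_absorbing_variant_drops_non_attenders(self):
        policy = SurveillancePolicy(missed_exam="drop")
        params = make_params(adherence_successive_surveillance=0.0)
        params.surveillance_result_dist = np.array([1.0, 0.0, 0.0, 0.0])
        pop = enter(n=500, high=True, age=55.0, policy=policy)
        tal = run_years(pop, params, policy)
        assert tal.surveillance.sum() == 500
        assert np.all(pop.status == EXITED)


class TestAgeCap:
    def test_no_exam_at_or_beyond_eighty(self):
        # entrants spread over ages, long horizon, everything negative
        params = make_params(adherence_successive_surveillance=0.4)
        params.surveillance_result_dist = np.array([0.0, 0.0, 1.0, 0.0])  # stay in
        pop = enter(n=3_000, high=True, age=76.0)
        tal = run_years(pop, params, SurveillancePolicy(), years=20, seed=9)
        assert tal.max_surv_exam_age < 80.0
        assert np.all(pop.status == EXITED)  # everyone aged out of surveillance
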