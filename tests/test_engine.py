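import numpy as np
import pytest

from crcdemand.cohort import (EXCLUDED, EXITED, ROUTINE, SURVEILLANCE,
                              Demography, Population)
from crcdemand.engine import (Tallies, draw_fit_result, draw_participation,
                              perform_index_colonoscopy, process_invitation,
                              run_simulation)
from crcdemand.parameters import (PointMass, StratifiedPrior,
                                  priors_from_config, read_config,
                                  sample_parameters)
from crcdemand.surveillance import SurveillancePolicy, policy_from_config
from crcdemand.cohort import demography_from_config

from conftest import pointify, small_cfg


def make_params(rng=None, **overrides):
    """A deterministic ParameterSet (point priors) with per-field overrides."""
    priors = priors_from_config(pointify(read_config()))
    kw = {}
    for name, value in overrides.items():
        if np.isscalar(value):
            stratified = name in ("exclusion_initial", "opportunistic",
                                  "participation_initial", "positivity_initial",
                                  "refusal")
            kw[name] = (StratifiedPrior.shared(PointMass(value)) if stratified
                        else PointMass(value))
        else:
            kw[name] = value
    priors = priors.with_overrides(**kw)
    return sample_parameters(priors, rng or np.random.default_rng(0))


def fresh_pop(n, age=60.0, t_invite=0.5):
    pop = Population(n)
    pop.age0[:] = age
    pop.next_invite[:] = t_invite
    return pop


class TestInvitation:
    def test_certain_exclusion_is_permanent(self, rng):
        params = make_params(exclusion_initial=1.0)
        pop = fresh_pop(100)
        tal = Tallies(20)
        idx = np.arange(100)
        invited, _ = process_invitation(pop, idx, np.full(100, 0.5), params, rng, tal)
        assert invited.size == 0
        assert np.all(pop.status == EXCLUDED)
        assert np.all(np.isinf(pop.next_invite))
        assert tal.invited.sum() == 0

    @pytest.mark.parametrize("recent,expected_interval", [(1.0, 4.0), (0.0, 2.0)])
    def test_opportunistic_deferral_depends_on_colonoscopy_recency(
            self, rng, recent, expected_interval):
        params = make_params(exclusion_initial=0.0, opportunistic=1.0,
                             opportunistic_recent_fraction=recent)
        pop = fresh_pop(50)
        tal = Tallies(20)
        invited, _ = process_invitation(pop, np.arange(50), np.full(50, 0.5),
                                        params, rng, tal)
        assert invited.size == 0
        np.testing.assert_allclose(pop.next_invite, 0.5 + expected_interval)

    def test_branch_counts_match_multinomial_expectation(self, rng):
        n = 10_000
        params = make_params(exclusion_initial=0.1, opportunistic=0.05)
        pop = fresh_pop(n)
        tal = Tallies(20)
        invited, _ = process_invitation(pop, np.arange(n), np.full(n, 0.5),
                                        params, rng, tal)
        excluded = int((pop.status == EXCLUDED).sum())
        deferred = n - excluded - invited.size
        # exact multinomial means: 1000 excluded, 0.9*0.05*n = 450 deferred
        assert abs(excluded - 1000) < 4 * np.sqrt(n * 0.1 * 0.9)
        assert abs(deferred - 450) < 4 * np.sqrt(n * 0.045)
        assert abs(invited.size - 8550) < 4 * np.sqrt(n * 0.855 * 0.145)

    def test_age_outside_target_range_is_contract_error(self, rng):
        params = make_params()
        pop = fresh_pop(5, age=72.0)
        with pytest.raises(ValueError, match="ages"):
            process_invitation(pop, np.arange(5), np.full(5, 0.5), params,
                               rng, Tallies(20))


class TestParticipation:
    def test_zero_probability_reinvites_after_two_years(self, rng):
        params = make_params(participation_initial=0.0)
        pop = fresh_pop(80)
        tal = Tallies(20)
        part, _ = draw_participation(pop, np.arange(80), np.full(80, 0.5),
                                     params, rng, tal)
        assert part.size == 0
        np.testing.assert_allclose(pop.next_invite, 2.5)
        assert not pop.prev_participant.any()

    def test_markov_stationary_participation_fraction(self):
        """With P(part|prev part)=0.85 and P(part|prev non-part)=0.30 the
        stationary participation fraction is 0.30/(1-0.85+0.30) = 2/3."""
        rng = np.random.default_rng(99)
        params = make_params(
            participation_initial=0.5,
            participation_successive_prev_participant=0.85,
            participation_successive_prev_nonparticipant=0.30,
        )
        n = 20_000
        pop = fresh_pop(n)
        tal = Tallies(60)
        for round_i in range(40):
            t = np.full(n, round_i + 0.5)
            pop.next_invite[:] = t
            part, _ = draw_participation(pop, np.arange(n), t, params, rng, tal)
        assert abs(part.size / n - 2 / 3) < 0.02


class TestFit:
    def test_zero_positivity_reinvites(self, rng):
        params = make_params(positivity_initial=0.0, positivity_successive=0.0)
        pop = fresh_pop(60)
        pos, _ = draw_fit_result(pop, np.arange(60), np.full(60, 0.5), params,
                                 rng, Tallies(20))
        assert pos.size == 0
        np.testing.assert_allclose(pop.next_invite, 2.5)
        assert np.all(pop.screen_count == 1)

    def test_certain_positivity(self, rng):
        params = make_params(positivity_initial=1.0)
        pop = fresh_pop(60)
        pos, _ = draw_fit_result(pop, np.arange(60), np.full(60, 0.5), params,
                                 rng, Tallies(20))
        assert pos.size == 60


class TestIndexColonoscopy:
    def _run(self, rng, n=100_000, mode="single", refusal=0.178, rate=0.123):
        params = make_params(refusal=refusal, second_look_rate=rate)
        params.second_look_mode = mode
        pop = fresh_pop(n)
        pop.screen_count[:] = 1
        tal = Tallies(20)
        perform_index_colonoscopy(pop, np.arange(n), np.full(n, 0.5), params,
                                  rng, tal, SurveillancePolicy())
        return tal

    def test_expected_total_exams_single_repeat_policy(self, rng):
        """1,000 positives x (1-0.178) uptake x 1.123 repeats = 923.1 exams."""
        n = 100_000
        tal = self._run(rng, n, mode="single")
        per_1000 = 1000 * tal.colono_index_total.sum() / n
        assert abs(per_1000 - 923.1) < 5.0

    def test_expected_total_exams_chained_repeat_policy(self, rng):
        """Chained second looks: uptake/(1-rate) = 0.822/0.877 = 937.3 per 1,000."""
        n = 100_000
        tal = self._run(rng, n, mode="chain")
        per_1000 = 1000 * tal.colono_index_total.sum() / n
        assert abs(per_1000 - 937.3) < 5.0

    def test_zero_second_look_rate_means_total_equals_first(self, rng):
        tal = self._run(rng, n=20_000, rate=0.0)
        assert tal.colono_index_total.sum() == tal.colono_index_first.sum()

    def test_outcome_tallies_sum_to_first_exams_and_route(self, rng):
        n = 50_000
        params = make_params(refusal=0.2)
        pop = fresh_pop(n)
        pop.screen_count[:] = 1
        tal = Tallies(20)
        perform_index_colonoscopy(pop, np.arange(n), np.full(n, 0.5), params,
                                  rng, tal, SurveillancePolicy())
        assert tal.index_outcome.sum() == tal.colono_index_first.sum()
        # refusers re-invited at +2, negatives at +10, cancers exited
        assert (pop.next_invite == 2.5).sum() > 0
        assert (pop.next_invite == 10.5).sum() == tal.index_outcome[:, 0].sum()
        assert (pop.status == EXITED).sum() == tal.index_outcome[:, 4].sum()
        assert (pop.status == SURVEILLANCE).sum() == tal.index_outcome[:, 2:4].sum()


class TestRunSimulation:
    def test_same_seed_bitwise_identical(self, small_bundle):
        priors, demog, policy = small_bundle
        a = run_simulation(priors, demog, 123, policy=policy)
        b = run_simulation(priors, demog, 123, policy=policy)
        for f in ("invited", "participants", "fit_positive",
                  "colono_index_total", "surveillance"):
            np.testing.assert_array_equal(getattr(a.yearly, f), getattr(b.yearly, f))
        assert a.adherence == b.adherence

    def test_zero_participation_zero_everything(self, default_cfg):
        cfg = small_cfg(default_cfg, size=5_000)
        cfg["screening"]["participation_initial"] = 0.0
        cfg["screening"]["participation_successive_prev_participant"] = 0.0
        cfg["screening"]["participation_successive_prev_nonparticipant"] = 0.0
        r = run_simulation(priors_from_config(cfg), demography_from_config(cfg),
                           7, policy=policy_from_config(cfg))
        assert r.yearly.participants.sum() == 0
        assert r.yearly.colono_index_total.sum() == 0
        assert r.yearly.surveillance.sum() == 0
        assert r.yearly.invited.sum() > 0

    def test_zero_positivity_no_colonoscopies_of_any_kind(self, default_cfg):
        cfg = small_cfg(default_cfg, size=5_000)
        cfg["screening"]["positivity_initial"] = 0.0
        cfg["screening"]["positivity_successive"] = 0.0
        r = run_simulation(priors_from_config(cfg), demography_from_config(cfg),
                           7, policy=policy_from_config(cfg))
        assert r.yearly.fit_positive.sum() == 0
        assert r.yearly.colono_index_total.sum() == 0
        assert r.yearly.surveillance.sum() == 0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_tally_nesting_and_conservation(self, small_bundle, seed):
        priors, demog, policy = small_bundle
        r = run_simulation(priors, demog, seed, policy=policy)
        y = r.yearly
        assert np.all(y.participants <= y.invited)
        assert np.all(y.fit_positive <= y.participants)
        assert np.all(y.colono_index_first <= y.fit_positive)
        assert np.all(y.colono_index_total >= y.colono_index_first)
        assert np.all(y.participants_successive <= y.participants)
        np.testing.assert_array_equal(y.index_outcome.sum(axis=1),
                                      y.colono_index_first)
        np.testing.assert_array_equal(y.surv_outcome.sum(axis=1), y.surveillance)
        # first simulation year cannot contain surveillance exams
        assert y.surveillance[0] == 0
        # age cap honored
        assert y.max_surv_exam_age < 80.0
        # conservation: every person who ever entered is in exactly one state
        assert sum(r.final_status.values()) == r.total_entered

    def test_mean_index_count_monotone_in_positivity(self, default_cfg):
        totals = []
        for pos in (0.03, 0.06):
            cfg = small_cfg(default_cfg, size=10_000)
            cfg["screening"]["positivity_initial"] = pos
            cfg["screening"]["positivity_successive"] = pos
            pri, dem, pol = (priors_from_config(cfg), demography_from_config(cfg),
                             policy_from_config(cfg))
            tot = np.mean([
                run_simulation(pri, dem, s, policy=pol).yearly.colono_index_total.sum()
                for s in (11, 12, 13)
            ])
            totals.append(tot)
        assert totals[1] > totals[0]
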