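# Default model configuration, calibrated so that the scenario-filtered
# ensemble reproduces the source program's published first/second-round
# aggregates (first-round participation 43.8%, FIT positivity 6.7%,
# colonoscopy uptake 82.2%, and the 20-year trajectories of invitations,
# participation, positivity and colonoscopy volumes).
#
# The person-level registry behind the original parameter estimates is not
# public, so stratum-level values and distribution families here are
# calibrated stand-ins: every stratified field shares its field mean across
# the 8 gender x age-group strata, with a `strata:` hook to differentiate
# them.  Probabilities are decimals in [0, 1]; intervals are integer years.
# `ess` is the Beta-prior effective sample size (alpha + beta) controlling
# run-to-run spread in the probabilistic sensitivity analysis; omit it for a
# fixed (point-mass) parameter.

demography:
  initial_size: 100000
  age_low: 50.0
  age_high: 70.0
  female_fraction: 0.5
  # yearly cohorts of 50-year-olds, linearly interpolated between the first
  # (start_year+1) and last (start_year+horizon-1) values
  entrants_first: 7200
  entrants_last: 7600
  gompertz:
    male: {a: 0.0033, b: 0.095}
    female: {a: 0.0015, b: 0.105}

screening:
  exclusion_initial: {mean: 0.064, ess: 500}
  exclusion_successive: {mean: 0.013, ess: 500}   # medical reasons only
  opportunistic: {mean: 0.022, ess: 500}
  opportunistic_recent_fraction: 0.5   # share with colonoscopy <= 3 y ago (deferred 4 y)
  participation_initial: {mean: 0.438, ess: 500}
  participation_successive_prev_participant: {mean: 0.87, ess: 12}
  participation_successive_prev_nonparticipant: {mean: 0.18, ess: 12}
  positivity_initial: {mean: 0.0666, ess: 500}
  positivity_successive: {mean: 0.0428, ess: 700}
  refusal: {mean: 0.178, ess: 500}
  second_look_rate: 0.123
  # "chain": every exam (repeats included) can indicate a further second look
  second_look_mode: chain
  # category shares: negative, low-, intermediate-, high-risk adenomas, cancer
  result_dist_initial: [0.320, 0.175, 0.275, 0.167, 0.063]
  result_dist_successive: [0.382, 0.192, 0.268, 0.114, 0.044]
  reinvite_intervals:
    non_participation: 2
    negative_fit: 2
    refusal: 2
    low_risk_adenoma: 2
    opportunistic_3_5y: 2
    opportunistic_le_3y: 4
    negative_index_colonoscopy: 10

surveillance:
  # negative, low-risk, intermediate/high-risk, cancer
  result_dist: [0.715, 0.257, 0.025, 0.003]
  entry_interval_high: 1
  entry_interval_intermediate: 3
  finding_interval: 3
  negative_intervals: [3, 5]
  negatives_to_exit: 3
  routine_return_after_negatives: 5
  routine_return_low_risk: 2
  age_cap: 80
  missed_exam: reschedule   # or "drop" (non-adherence absorbing)
  retry_interval: 0.25

psa:
  adherence: {low: 0.20, high: 0.90}

run:
  start_year: 2015
  horizon: 20
  n_runs: 1750
  filter:
    participation: [0.40, 0.60]
    positivity: [0.047, 0.068]
    adherence: [0.35, 0.70]
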