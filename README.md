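# crcdemand

**Forecasting the colonoscopy demand generated by a population-based
colorectal-cancer screening program.**

Population-based CRC screening with a biennial fecal immunochemical test
(FIT) commits a health system to colonoscopies for decades: every positive
test needs a diagnostic colonoscopy, and every intermediate- or high-risk
adenoma removed puts its owner on a years-long surveillance schedule.
Endoscopy capacity, not screening uptake, is usually the binding
constraint, and the surveillance load builds up with a long delay that
simple per-round arithmetic misses.  `crcdemand` is a discrete-event
microsimulation built for the people who have to plan that capacity: it
simulates every person in a target population of 100,000 aged 50-69 over a
20-year horizon — invitation, exclusion, opportunistic screening,
participation, FIT result, colonoscopy and its second-look repeats, and
guideline post-polypectomy surveillance to age 79 — and reports yearly
colonoscopy demand with uncertainty from a probabilistic sensitivity
analysis.

The model's core quantities, per calendar year y:

* **Index colonoscopies** `C_y` — exams after a positive FIT, including
  second-look repeats, which chain with rate q = 0.123 so that
  E[exams per attended positive] = 1/(1-q);
* **Surveillance colonoscopies** `S_y` — attended exams of the
  post-polypectomy scheme (high risk: first exam +1 y; intermediate:
  +3 y; negatives extend 3 → 5 y; third consecutive negative returns to
  routine screening; age cap 79);
* a **run filter** keeping replications whose 20-year mean participation,
  FIT positivity and surveillance adherence lie in the currently observed
  ranges ([40, 60]%, [4.7, 6.8]%, [35, 70]%);
* a **demand meta-regression** across replications,
  `count ~ participation + positivity + adherence + t + interactions(t) +
  positivity:participation`, whose coefficients read directly as "extra
  colonoscopies per +1 percentage point".

Screening probabilities are stratified by gender and age group (50-54,
55-59, 60-64, 65-69) and drawn per run from Beta priors (probabilistic
sensitivity analysis); colonoscopy outcome distributions are empirical and
fixed.  There is no natural-history model of colorectal neoplasia — this
is a demand forecaster, not an outcomes model (see `docs/methods.md`).

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_run_ensemble.py 400 1      # simulate 400 replications
python analysis/02_scenario_tables.py         # filter + yearly demand tables
python analysis/03_sensitivity_metamodel.py   # demand meta-regression
python analysis/04_registry_calibration.py    # synthetic-registry round trip
```

`01` simulates the probabilistic ensemble and prints the run-level spread
that the scenario filter will act on:

```
simulated 400 replications in 121s
run-level 20-year mean participation: 0.503 (sd 0.103)
run-level 20-year mean FIT positivity: 0.0506 (sd 0.0054)
```

`02` applies the current-scenario filter and tabulates demand:

```
current-scenario filter kept 91/400 runs
colonoscopies after a positive FIT: 1206 (2015) -> 1475 (2034); yearly mean 1255
surveillance colonoscopies:          0 (2015) -> 1007 (2034)
overall demand 1206 -> 2482: x2.1 over the horizon
```

Read: the program starts at ~1,200 index colonoscopies per year per
100,000 inhabitants; twenty years in, surveillance adds another ~1,000
exams per year, doubling the overall demand even though FIT positivity
*falls* as successive screens come to dominate.  `03` quantifies the
drivers:

```
+1% FIT positivity at participation 70%, final year: +336 colonoscopies after a positive FIT (se 2.0)
+1% participation at positivity 4%, final year: +21.4 colonoscopies after a positive FIT (se 0.11)
+1% surveillance adherence, final year: +0.58 surveillance colonoscopies (se 0.09)
```

A one-point rise in positivity moves demand about as much as a ten-point
rise in participation; adherence barely moves it (missed surveillance
exams are recalled, so adherence shifts timing more than volume).  `04`
closes the calibration loop on a synthetic two-round registry: every
screening-chain probability is re-estimated from 767,264 generated
person-round records with exact binomial intervals that cover the known
truth.

The same pipeline is available as a CLI
(`crcdemand simulate|sensitivity|make-registry|estimate|reproduce`), and
every model constant — demography, probabilities and their spreads,
surveillance transition table, filter bounds — lives in a YAML config
(`src/crcdemand/data/default_config.yaml`) that `--config` overrides
field by field.

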