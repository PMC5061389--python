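"""Close the calibration loop on a synthetic screening registry.

Generates a synthetic two-round person-level registry (the stand-in for the
source program's non-public round 1-2 data) under known parameters,
re-estimates every screening-chain probability with exact binomial
intervals, and reports how well the estimates recover the truth.

Usage: python analysis/04_registry_calibration.py [n_per_stratum] [seed]
"""

import sys
from pathlib import Path

import numpy as np

from crcdemand.parameters import priors_from_config, read_config, sample_parameters
from crcdemand.synthetic_registry import estimate_parameters, generate_registry

n = int(sys.argv[1]) if len(sys.argv) > 1 else 50_000
seed = int(sys.argv[2]) if len(sys.argv) > 2 else 1

out = Path("results")
out.mkdir(exist_ok=True)

rng = np.random.default_rng(seed)
cfg = read_config()
truth = sample_parameters(priors_from_config(cfg), rng)
reg = generate_registry(truth, n, rng)
reg.to_csv(out / "synthetic_registry.csv", index=False)
est = estimate_parameters(reg)
est.to_csv(out / "registry_estimates.csv", index=False)

print(f"registry: {len(reg):,} person-round records "
      f"({n:,} persons per stratum x 8 strata, 2 rounds)")
checks = [
    ("participation_initial", "male", "60-64", truth.participation_initial[0, 2]),
    ("positivity_initial", "female", "50-54", truth.positivity_initial[1, 0]),
    ("refusal", "male", "65-69", truth.refusal[0, 3]),
    ("positivity_successive", "all", "all", truth.positivity_successive),
    ("participation_successive_prev_participant", "all", "all",
     truth.participation_successive_prev_participant),
]
by = est.set_index(["parameter", "gender", "age_group"])
n_cov = 0
for key in checks:
    row = by.loc[key[:3]]
    covered = row["lo95"] <= key[3] <= row["hi95"]
    n_cov += covered
    print(f"  {key[0]} [{key[1]}/{key[2]}]: truth {key[3]:.4f}, "
          f"estimate {row['estimate']:.4f} "
          f"[{row['lo95']:.4f}, {row['hi95']:.4f}] "
          f"{'covered' if covered else 'MISSED'}")
print(f"{n_cov}/{len(checks)} spot-checked intervals cover the truth")
print(f"wrote {out/'synthetic_registry.csv'} and {out/'registry_estimates.csv'}")
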