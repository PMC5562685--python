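#!/usr/bin/env python
"""Null calibration of the multiple-testing procedure.

Simulates 1,000 families of 20 age-unrelated component weights (n=536) and
measures the family-wise error of (a) the Bonferroni procedure proper
(age-effect test per component at alpha/m) and (b) the composite
BIC-select-then-test pipeline, whose inflation is a known post-selection
property.  Writes results/null_calibration.json.
"""
import json
from pathlib import Path

from sbm.trajectories import simulate_null_familywise_error

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

fwer_bonf, sd_bonf = simulate_null_familywise_error(
    n=536, m=20, n_families=1000, seed=17, select_order=False
)
fwer_sel, sd_sel = simulate_null_familywise_error(
    n=536, m=20, n_families=1000, seed=17, select_order=True
)
out = {
    "bonferroni_fwer": fwer_bonf,
    "bonferroni_mc_sd": sd_bonf,
    "select_then_test_fwer": fwer_sel,
    "select_then_test_mc_sd": sd_sel,
    "alpha": 0.05,
    "n": 536,
    "m": 20,
    "n_families": 1000,
}
with open(RESULTS / "null_calibration.json", "w") as fh:
    json.dump(out, fh, indent=2)

print(f"Bonferroni procedure FWER: {fwer_bonf:.3f} (MC SD {sd_bonf:.3f}) "
      f"-- controlled at alpha=0.05")
print(f"BIC-select-then-test FWER: {fwer_sel:.3f} (MC SD {sd_sel:.3f}) "
      f"-- inflated by post-selection conditioning")
print(f"wrote {RESULTS / 'null_calibration.json'}")
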