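#!/usr/bin/env python
"""Parameter-recovery experiment: can the pipeline recover the generating
networks and their age trajectories?

Over several seeds: synthesize a cohort at the default study conditions
(K=4 networks, n=200, loading SNR >= 3), remove confounds, decompose,
optimally match estimated to true components, and fit BIC-selected age
trajectories to the recovered loadings.  Writes
results/recovery_trajectories.tsv with one row per (seed, component).
"""
from pathlib import Path

import numpy as np
import pandas as pd

from sbm import ica, preprocess, synthetic, trajectories
from sbm.volume import default_grid

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

N_SEEDS = 5
grid = default_grid()
rows = []
for seed in range(N_SEEDS):
    gt = synthetic.make_ground_truth(grid, K=4, seed=seed)
    cohort = synthetic.sample_cohort(synthetic.scaled_age_bins(200),
                                     seed=seed + 99991)
    ages = cohort["age"].to_numpy()
    dm = synthetic.synthesize(gt, cohort)
    dm = preprocess.residualize(dm, preprocess.build_confound_design(cohort))
    dec = ica.decompose(dm, K=4, seed=seed)
    rep = ica.match_components(dec, gt)
    for est_idx in range(4):
        true_idx = int(rep.permutation[est_idx])
        spec = gt.loading_specs[true_idx]
        w = dec.mixing[:, est_idx] * rep.signs[est_idx]
        tf = trajectories.fit_component(w, ages, m=4, component=est_idx)
        rows.append({
            "seed": seed,
            "true_component": true_idx,
            "true_order": spec.order,
            "selected_order": tf.selected_order,
            "spatial_corr": float(rep.spatial_correlation[est_idx]),
            "beta_high": tf.beta_high,
            "true_beta_sign": float(np.sign(spec.coefficients[-1])),
            "t": tf.t,
            "p": tf.p,
        })

table = pd.DataFrame(rows)
table.to_csv(RESULTS / "recovery_trajectories.tsv", sep="\t", index=False)

acc = (table["selected_order"] == table["true_order"]).mean()
print(f"{N_SEEDS} seeds x 4 components:")
print(f"  mean matched spatial |correlation| = {table['spatial_corr'].mean():.3f}")
print(f"  BIC selected the generating order in {acc:.0%} of components")
ok_order = table[table["selected_order"] == table["true_order"]]
sign_ok = (np.sign(ok_order["beta_high"]) == ok_order["true_beta_sign"]).all()
print(f"  every recovered highest-order beta carries the generating sign: {sign_ok}")
print(f"wrote {RESULTS / 'recovery_trajectories.tsv'}")
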