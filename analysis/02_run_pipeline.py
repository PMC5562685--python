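#!/usr/bin/env python
"""Run the full synthetic pipeline (smooth -> residualize -> ICA -> maps ->
trajectories) and report what it produced.

Writes the complete run directory under results/pipeline_run/ (mixing and
cluster/trajectory/sensitivity tables, per-component z-map NIfTIs,
convergence and recovery reports, manifest with checksums).
"""
import json
from pathlib import Path

import pandas as pd

from sbm.pipeline import RunConfig, run_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"
cfg = RunConfig(mode="synthetic", n_components=4, k_true=4, n_subjects=200,
                seed=1, outdir=str(RESULTS / "pipeline_run"))
run_dir = run_pipeline(cfg)

conv = json.loads((run_dir / "convergence.json").read_text())
rec = json.loads((run_dir / "recovery.json").read_text())
clusters = pd.read_csv(run_dir / "clusters.tsv", sep="\t")
traj = pd.read_csv(run_dir / "trajectories.tsv", sep="\t")

print(f"run directory: {run_dir}")
print(f"ICA converged={conv['converged']} after {conv['iterations']} "
      f"iterations; retained variance {conv['retained_variance']:.4f}")
print(f"recovery: matched spatial |r| = "
      f"{[round(c, 3) for c in rec['spatial_correlation']]} "
      f"(mean {rec['mean_spatial_correlation']:.3f})")
print(f"z >= 3 clusters per component: "
      f"{clusters.groupby('component').size().to_dict()}")
print("trajectory report:")
print(traj[["component", "selected_order", "r2", "beta_high", "t", "p",
            "significant"]].to_string(index=False))
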