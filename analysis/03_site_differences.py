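#!/usr/bin/env python
"""Do site differences in FA/MD disappear after harmonization?

Runs the matched-control experiment with an injected order-2 site effect
(gamma_2 = 0.8, SNR 30, 20 controls per site): skeleton-mean effect sizes
and a voxelwise max-statistic permutation test over the white-matter mask,
before and after harmonization. Writes results/site_differences.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from rishharm import experiments

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--permutations", type=int, default=1000)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

res = experiments.run_site_effect_experiment(args.seed, args.permutations)
args.out.mkdir(parents=True, exist_ok=True)
table = pd.DataFrame([
    {"arm": "before", "fa_d": res["pre_control_fa_d"], "md_d": res["pre_control_md_d"],
     "significant_voxels": res["pre_significant_voxels"]},
    {"arm": "after", "fa_d": res["post_control_fa_d"], "md_d": res["post_control_md_d"],
     "significant_voxels": res["post_significant_voxels"]},
]).round(3)
table.to_csv(args.out / "site_differences.csv", index=False)

print(table.to_string(index=False))
print(f"\ncontrol-vs-control FA d shrinks from {res['pre_control_fa_d']:.2f} to "
      f"{res['post_control_fa_d']:.2f}; significant voxels from "
      f"{res['pre_significant_voxels']} to {res['post_significant_voxels']} "
      f"of {res['n_wm_voxels_tested']} tested")
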