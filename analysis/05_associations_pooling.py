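#!/usr/bin/env python
"""WMH-volume associations within sites and on pooled patients.

Runs the strong-site-effect disease study (gamma_2 = 0.8, 60 patients per
site): per-site regressions of skeleton MD on Box-Cox WMH volume (the
generator induces a population R^2 of 0.6), and pooled-patient regressions
before vs after harmonization, where removing FA site offsets should
improve the pooled fit. Writes results/associations.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from rishharm import experiments

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

res = experiments.run_association_experiment(args.seed)
args.out.mkdir(parents=True, exist_ok=True)
rows = [
    {"quantity": "induced population R2 (MD ~ boxcox WMH)", "value": res["induced_population_r2"]},
    {"quantity": "siteA MD R2", "value": res["siteA_md_wmh_r2"]},
    {"quantity": "siteB MD R2", "value": res["siteB_md_wmh_r2"]},
    {"quantity": "pooled FA R2 before", "value": res["pooled_fa_r2_before"]},
    {"quantity": "pooled FA R2 after", "value": res["pooled_fa_r2_after"]},
    {"quantity": "pooled MD R2 before", "value": res["pooled_md_r2_before"]},
    {"quantity": "pooled MD R2 after", "value": res["pooled_md_r2_after"]},
]
table = pd.DataFrame(rows).round(3)
table.to_csv(args.out / "associations.csv", index=False)
print(table.to_string(index=False))
print(f"\npooled FA R2 improves from {res['pooled_fa_r2_before']:.2f} to "
      f"{res['pooled_fa_r2_after']:.2f} after harmonization")
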