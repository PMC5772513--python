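#!/usr/bin/env python
"""CR modularity tests: four hypotheses x two components x five sources.

For the total sample and each group, tests every modularity hypothesis on
the symmetric and asymmetric (FA) shape components with the covariance-ratio
statistic and 999 landmark permutations.  Subsamples reuse the shared joint
superimposition.  Writes the modularity table to results/table1_modularity.csv.
"""

from pathlib import Path

import pandas as pd

from symmorph.landmark_io import (
    load_partition,
    read_group_labels,
    read_landmarks_csv,
    read_symmetry_map,
)
from symmorph.pipeline import RunConfig, run_analysis

DATA = Path("results/data")
OUT = Path("results")

configs = read_landmarks_csv(DATA / "landmarks.csv")
smap = read_symmetry_map(DATA / "symmetry_map.json")
partitions = [load_partition(p) for p in sorted(DATA.glob("partition_*.json"))]
groups = read_group_labels(DATA / "groups.csv")

cfg = RunConfig(seed=1, n_perm_cr=999, n_perm_matrix=1)  # matrices unused here
result = run_analysis(configs, smap, partitions, groups, cfg)
table1 = result["table1_modularity"]
table1.to_csv(OUT / "table1_modularity.csv", index=False)

print(table1.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
total = table1[table1["source"] == "total"]
strongest = total.loc[total["CR"].idxmin()]
print(f"\nstrongest modularity signal in the total sample: "
      f"{strongest['hypothesis']} / {strongest['component']} "
      f"(CR={strongest['CR']:.4f}, p={strongest['p_value']:.3f})")
n_sig = (table1["p_value"] <= 0.05).sum()
print(f"{n_sig}/{len(table1)} hypothesis tests significant at alpha=0.05; "
      "the true (functional) partition generated the data, and overlapping "
      "hypotheses inherit part of its signal")
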