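#!/usr/bin/env python
"""Similarity of individual and FA covariance matrices.

Two complementary comparisons:

* the full-space matrix correlation between the individual (symmetric) and
  FA covariance matrices with a 10,000-iteration landmark-permutation test —
  structurally bounded far below 1 because the two components occupy
  orthogonal subspaces of the bilateral landmark space;
* the proportionality check on the paired-left-landmark sub-blocks of the
  generated deviation covariances, where Sigma_FA = c * Sigma_ind is
  identifiable.

Writes results/table2_matrix_correlations.csv.
"""

from pathlib import Path

from symmorph.integration import (
    build_covariance_set,
    landmark_subblock,
    matrix_permutation_test,
)
from symmorph.landmark_io import read_landmarks_csv, read_symmetry_map
from symmorph.pipeline import stage_rng
from symmorph.symmetry_gpa import decompose_symmetry

import pandas as pd

DATA = Path("results/data")
OUT = Path("results")
SEED = 1
N_PERM = 10000

configs = read_landmarks_csv(DATA / "landmarks.csv")
smap = read_symmetry_map(DATA / "symmetry_map.json")
_, decomp = decompose_symmetry(configs, smap)
covset = build_covariance_set(decomp)

rows = []
for include_diag in (True, False):
    rng = stage_rng(SEED, f"matcorr/total/individual_x_fa/{include_diag}")
    res = matrix_permutation_test(covset.individual, covset.fa, d=decomp.d,
                                  n_perm=N_PERM, seed=rng,
                                  include_diagonal=include_diag)
    rows.append({"comparison": "individual x fa (full space)",
                 "include_diagonal": include_diag,
                 "r": res.r, "p_value": res.p_value, "n_perm": N_PERM})

# one-side sub-block comparison: the frame where proportionality is visible
left = [l for l, _ in smap.pairs]
sub_i = landmark_subblock(covset.individual, left, decomp.d)
sub_f = landmark_subblock(covset.fa, left, decomp.d)
rng = stage_rng(SEED, "matcorr/total/individual_x_fa/left_block")
res = matrix_permutation_test(sub_i, sub_f, d=decomp.d, n_perm=N_PERM,
                              seed=rng)
rows.append({"comparison": "individual x fa (paired-left sub-block)",
             "include_diagonal": True,
             "r": res.r, "p_value": res.p_value, "n_perm": N_PERM})

table2 = pd.DataFrame(rows)
table2.to_csv(OUT / "table2_matrix_correlations.csv", index=False)
print(table2.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nfull-space r is small despite proportional generating structure "
      "(orthogonal symmetric/antisymmetric subspaces); the one-side "
      "sub-block comparison recovers the proportionality")
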