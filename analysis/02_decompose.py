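#!/usr/bin/env python
"""Object-symmetry Procrustes decomposition and ANOVA of the study dataset.

Doubles the dataset with reflected-relabeled copies, superimposes jointly,
splits each face into symmetric and asymmetric components, and partitions
the Procrustes variation into individual, side (directional asymmetry) and
individual x side (fluctuating asymmetry) effects.

Reads results/data/; writes the decomposition export and ANOVA table under
results/decomposition/.
"""

from pathlib import Path

import numpy as np

from symmorph.landmark_io import read_landmarks_csv, read_symmetry_map
from symmorph.pipeline import export_decomposition
from symmorph.symmetry_gpa import decompose_symmetry, procrustes_anova

DATA = Path("results/data")
OUT = Path("results/decomposition")

configs = read_landmarks_csv(DATA / "landmarks.csv")
smap = read_symmetry_map(DATA / "symmetry_map.json")

sample, decomp = decompose_symmetry(configs, smap)
anova = procrustes_anova(decomp)

OUT.mkdir(parents=True, exist_ok=True)
export_decomposition(decomp, OUT)
anova.to_frame().to_csv(OUT / "procrustes_anova.csv", index=False)

recon_gap = np.abs(decomp.symmetric + decomp.asymmetric
                   - sample.aligned[:decomp.n]).max()
da_norm = float(np.sqrt((decomp.da_mean ** 2).sum()))
print(f"decomposed {decomp.n} specimens; GPA converged in "
      f"{sample.n_iterations} iterations")
print(f"reconstruction identity gap: {recon_gap:.2e} (should be ~machine eps)")
print(f"directional asymmetry magnitude (Procrustes units): {da_norm:.5f}")
print(anova.to_frame().to_string(index=False))
ms = anova.ms
print(f"MS individual / MS ind x side = "
      f"{ms['individual'] / ms['individual_x_side']:.2f} "
      "(among-individual variation dominates FA, as designed)")
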