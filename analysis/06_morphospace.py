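#!/usr/bin/env python
"""PCA morphospaces of the symmetric and asymmetric components.

Projects specimens onto principal components of each shape component,
summarizes each group by its score centroid and 90% coverage ellipse, and
saves static scatter plots.  Writes score CSVs, ellipse summaries and PNGs
under results/morphospace/.
"""

from pathlib import Path

import pandas as pd

from symmorph.landmark_io import (
    read_group_labels,
    read_landmarks_csv,
    read_symmetry_map,
)
from symmorph.morphospace import group_summary, pca, plot_scores, scores_frame
from symmorph.symmetry_gpa import decompose_symmetry

DATA = Path("results/data")
OUT = Path("results/morphospace")

configs = read_landmarks_csv(DATA / "landmarks.csv")
smap = read_symmetry_map(DATA / "symmetry_map.json")
groups = read_group_labels(DATA / "groups.csv")

_, decomp = decompose_symmetry(configs, smap)
labels = [groups.get(sid, "unlabeled") for sid in decomp.specimen_ids]

OUT.mkdir(parents=True, exist_ok=True)
for comp in ("symmetric", "asymmetric"):
    rows = decomp.flat("fa" if comp == "asymmetric" else comp)
    res = pca(rows)
    scores_frame(res, decomp.specimen_ids).to_csv(
        OUT / f"pca_scores_{comp}.csv", index=False)
    ellipses = group_summary(res.scores, labels, coverage=0.90)
    pd.DataFrame([
        {"group": e.group, "n": e.n,
         "centroid_pc1": e.centroid[0], "centroid_pc2": e.centroid[1],
         "semi_axis_major": e.semi_axes[0], "semi_axis_minor": e.semi_axes[1],
         "angle_rad": e.angle}
        for e in ellipses.values()
    ]).to_csv(OUT / f"ellipses_{comp}.csv", index=False)
    plot_scores(res, labels, coverage=0.90, path=OUT / f"pca_{comp}.png")
    print(f"{comp}: PC1 {100 * res.proportion[0]:.1f}%, "
          f"PC2 {100 * res.proportion[1]:.1f}% of variance; "
          f"{len(ellipses)} group ellipses")

print(f"scores, ellipse summaries and plots written to {OUT}")
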