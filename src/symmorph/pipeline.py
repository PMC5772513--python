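"""End-to-end orchestration: decompose -> modularity -> matrix similarity ->
integration -> morphospace, per group and shape component.

The pipeline consumes a landmark dataset, a symmetry map, one or more module
partitions and optional group labels, and emits the five result tables as
CSV files plus a manifest recording every resolved parameter.

Randomness: one global seed expands into independent named substreams (one
per permutation test), so adding or reordering a stage never perturbs
another stage's draws and reruns are byte-identical.

Subsample analyses reuse the decomposition from the joint superimposition of
the total dataset (one consistent shape space); a flag re-superimposes each
subsample separately instead.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .landmark_io import (
    LandmarkConfiguration,
    ModulePartition,
    SymmetryMap,
    read_group_labels,
    read_landmarks_csv,
    read_symmetry_map,
    read_tps,
    load_partition,
)
from .symmetry_gpa import decompose_symmetry, procrustes_anova, SymmetryDecomposition
from .modularity import cr_test
from .integration import (
    build_covariance_set,
    integration_regressions,
    integration_table,
    matrix_permutation_test,
)
from .morphospace import pca, group_summary, scores_frame

__all__ = ["RunConfig", "run_pipeline", "run_analysis", "stage_rng"]

COMPONENTS = ("symmetric", "asymmetric")


def stage_rng(seed: int | None, stage: str) -> np.random.Generator:
    """Independent, named random substream derived from the global seed."""
    tag = zlib.crc32(stage.encode())
    if seed is None:
        return np.random.default_rng([tag])
    return np.random.default_rng([int(seed), tag])


@dataclass
class RunConfig:
    """Resolved inputs and options of one pipeline run."""

    landmarks: str | None = None          # TPS or CSV path
    symmetry_map: str | None = None
    partitions: list[str] = field(default_factory=list)
    groups: str | None = None
    output_dir: str = "results"
    components: tuple[str, ...] = COMPONENTS
    n_perm_cr: int = 999
    n_perm_matrix: int = 10000
    seed: int = 0
    remove_da: bool = True
    include_diagonal_modes: tuple[bool, ...] = (True, False)
    resuperimpose_groups: bool = False
    alpha_band: float = 0.01
    scale: bool = True

    def validate_paths(self) -> None:
        for p in [self.landmarks, self.symmetry_map, self.groups, *self.partitions]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if self.n_perm_cr < 1 or self.n_perm_matrix < 1:
            raise ValueError("permutation counts must be >= 1")


def _check_groups(groups: dict[str, str] | None,
                  specimen_ids: Sequence[str]) -> dict[str, str] | None:
    if not groups:
        return None
    known = set(specimen_ids)
    for sid in groups:
        if sid not in known:
            raise ValueError(
                f"group file references unknown specimen {sid!r} "
                f"(group {groups[sid]!r})"
            )
    return dict(groups)


def _subsample(decomp: SymmetryDecomposition, ids: list[str]) -> SymmetryDecomposition:
    """Restrict a decomposition to a subset of specimens (shared shape space).

    The directional-asymmetry mean is re-estimated within the subsample so FA
    deviations are centered per source.
    """
    pos = {sid: i for i, sid in enumerate(decomp.specimen_ids)}
    idx = [pos[s] for s in ids]
    asym = decomp.asymmetric[idx]
    return SymmetryDecomposition(
        specimen_ids=list(ids),
        symmetric=decomp.symmetric[idx],
        asymmetric=asym,
        da_mean=asym.mean(axis=0),
        consensus=decomp.consensus,
        centroid_sizes=decomp.centroid_sizes[idx],
        smap=decomp.smap,
        n_replicates=decomp.n_replicates,
        remove_da=decomp.remove_da,
        symmetric_by_rep=(decomp.symmetric_by_rep[idx]
                          if decomp.symmetric_by_rep is not None else None),
        asymmetric_by_rep=(decomp.asymmetric_by_rep[idx]
                           if decomp.asymmetric_by_rep is not None else None),
    )


def run_analysis(
    configs: Sequence[LandmarkConfiguration],
    smap: SymmetryMap,
    partitions: Sequence[ModulePartition],
    groups: dict[str, str] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run the full in-memory analysis; returns tables and result objects."""
    cfg = config or RunConfig()
    sample, decomp = decompose_symmetry(
        configs, smap, scale=cfg.scale, remove_da=cfg.remove_da
    )
    groups = _check_groups(groups, decomp.specimen_ids)
    anova = procrustes_anova(decomp)

    sources: dict[str, SymmetryDecomposition] = {"total": decomp}
    if groups:
        for g in sorted(set(groups.values())):
            ids = [sid for sid in decomp.specimen_ids if groups.get(sid) == g]
            if len(ids) < 3:
                continue
            if cfg.resuperimpose_groups:
                sub_configs = [c for c in configs if c.specimen_id in set(ids)]
                _, sub = decompose_symmetry(sub_configs, smap, scale=cfg.scale,
                                            remove_da=cfg.remove_da)
            else:
                sub = _subsample(decomp, ids)
            sources[g] = sub

    d = decomp.d

    # ---- Table 1: CR modularity tests
    t1_rows = []
    for source, dec in sources.items():
        for part in partitions:
            for comp in cfg.components:
                rng = stage_rng(cfg.seed, f"cr/{source}/{part.name}/{comp}")
                res = cr_test(dec.flat("fa" if comp == "asymmetric" else comp),
                              part, d=d, n_perm=cfg.n_perm_cr, seed=rng)
                t1_rows.append({"source": source, "hypothesis": part.name,
                                "component": comp, "CR": res.cr_observed,
                                "p_value": res.p_value, "n_perm": res.n_perm})
    table1 = pd.DataFrame(t1_rows)

    # ---- Table 2: covariance-matrix correlations
    t2_rows = []
    covsets = {}
    for source, dec in sources.items():
        covset = build_covariance_set(dec)
        covsets[source] = covset
        mats = covset.matrices()
        names = list(mats)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                for inc in cfg.include_diagonal_modes:
                    rng = stage_rng(cfg.seed,
                                    f"matcorr/{source}/{names[i]}x{names[j]}/{inc}")
                    res = matrix_permutation_test(
                        mats[names[i]], mats[names[j]], d=d,
                        n_perm=cfg.n_perm_matrix, seed=rng,
                        include_diagonal=inc)
                    t2_rows.append({"source": source,
                                    "pair": f"{names[i]} x {names[j]}",
                                    "include_diagonal": inc,
                                    "r": res.r, "p_value": res.p_value,
                                    "n_perm": res.n_perm})
    table2 = pd.DataFrame(t2_rows)

    # ---- Table 3: integration metrics; Tables 4 & 5: regressions
    t3_frames, t45_rows = [], []
    flags_frames = []
    for source, covset in covsets.items():
        t3 = integration_table(covset, list(partitions), d,
                               components=cfg.components)
        t3.insert(0, "source", source)
        t3_frames.append(t3)
        for comp in cfg.components:
            reg_int, reg_fa, flags = integration_regressions(
                t3, comp, alpha_band=cfg.alpha_band)
            flags.insert(0, "source", source)
            flags_frames.append(flags)
            for which, reg in (("evstv_on_tvc", reg_int),
                               ("fa_on_evstv", reg_fa)):
                t45_rows.append({
                    "regression": which, "component": comp, "source": source,
                    "slope": reg.slope, "intercept": reg.intercept,
                    "r2": reg.r2, "rmse": reg.rmse,
                    "correlation": reg.correlation,
                    "df_model": reg.df_model, "df_error": reg.df_error,
                    "ss_model": reg.ss_model, "ms_model": reg.ms_model,
                    "f": reg.f, "p_value": reg.p_value,
                })
    table3 = pd.concat(t3_frames, ignore_index=True)
    table45 = pd.DataFrame(t45_rows)
    table4 = table45[table45["regression"] == "evstv_on_tvc"].drop(columns="regression")
    table5 = table45[table45["regression"] == "fa_on_evstv"].drop(columns="regression")
    flags_table = pd.concat(flags_frames, ignore_index=True)

    # ---- Morphospaces
    pca_results = {}
    scores_tables = {}
    ellipse_rows = []
    for comp in cfg.components:
        res = pca(decomp.flat("fa" if comp == "asymmetric" else comp))
        pca_results[comp] = res
        scores_tables[comp] = scores_frame(res, decomp.specimen_ids)
        if groups:
            labels = [groups.get(sid, "unlabeled") for sid in decomp.specimen_ids]
            for ell in group_summary(res.scores, labels).values():
                ellipse_rows.append({
                    "component": comp, "group": ell.group, "n": ell.n,
                    "centroid_pc1": ell.centroid[0], "centroid_pc2": ell.centroid[1],
                    "semi_axis_major": ell.semi_axes[0],
                    "semi_axis_minor": ell.semi_axes[1],
                    "angle_rad": ell.angle, "coverage": ell.coverage,
                })
    ellipses = pd.DataFrame(ellipse_rows)

    return {
        "decomposition": decomp, "aligned": sample, "anova": anova,
        "sources": sources, "covariances": covsets,
        "table1_modularity": table1,
        "table2_matrix_correlations": table2,
        "table3_integration": table3,
        "table4_evstv_on_tvc": table4,
        "table5_fa_on_evstv": table5,
        "integration_flags": flags_table,
        "pca": pca_results, "scores": scores_tables, "ellipses": ellipses,
    }


def export_decomposition(decomp: SymmetryDecomposition, outdir: Path) -> None:
    """CSV of flattened components plus a JSON sidecar with the means."""
    n = decomp.n
    sym = decomp.flat("symmetric")
    asym = decomp.flat("asymmetric")
    cols = {}
    for prefix, arr in (("sym", sym), ("asym", asym)):
        for j in range(arr.shape[1]):
            cols[f"{prefix}_{j}"] = arr[:, j]
    df = pd.DataFrame({"specimen_id": decomp.specimen_ids, **cols})
    df.to_csv(outdir / "decomposition.csv", index=False)
    sidecar = {
        "consensus": decomp.consensus.tolist(),
        "da_mean": decomp.da_mean.tolist(),
        "centroid_sizes": dict(zip(decomp.specimen_ids,
                                   decomp.centroid_sizes.tolist())),
        "n_replicates": decomp.n_replicates,
        "remove_da": decomp.remove_da,
    }
    (outdir / "decomposition.json").write_text(json.dumps(sidecar, indent=2))


def run_pipeline(
    config: RunConfig,
    configs: Sequence[LandmarkConfiguration] | None = None,
    smap: SymmetryMap | None = None,
    partitions: Sequence[ModulePartition] | None = None,
    groups: dict[str, str] | None = None,
) -> dict:
    """Load inputs (unless given in memory), run the analysis, write outputs.

    Any stage failure aborts with the stage name and offending input in the
    exception message.  Returns the :func:`run_analysis` result dict.
    """
    stage = "load"
    try:
        if configs is None:
            config.validate_paths()
            path = Path(config.landmarks)
            configs = (read_tps(path) if path.suffix.lower() == ".tps"
                       else read_landmarks_csv(path))
        if smap is None:
            smap = read_symmetry_map(config.symmetry_map)
        if partitions is None:
            partitions = [load_partition(p) for p in config.partitions]
        if groups is None and config.groups:
            groups = read_group_labels(config.groups)

        stage = "analysis"
        result = run_analysis(configs, smap, partitions, groups, config)

        stage = "write"
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("table1_modularity", "table2_matrix_correlations",
                     "table3_integration", "table4_evstv_on_tvc",
                     "table5_fa_on_evstv", "integration_flags", "ellipses"):
            result[name].to_csv(outdir / f"{name}.csv", index=False)
        for comp, df in result["scores"].items():
            df.to_csv(outdir / f"pca_scores_{comp}.csv", index=False)
        result["anova"].to_frame().to_csv(outdir / "procrustes_anova.csv",
                                          index=False)
        export_decomposition(result["decomposition"], outdir)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "n_specimens": result["decomposition"].n,
            "k": result["decomposition"].k,
            "d": result["decomposition"].d,
            "n_replicates": result["decomposition"].n_replicates,
            "partitions": [p.name for p in partitions],
            "sources": list(result["sources"]),
            "options": {k: v for k, v in asdict(config).items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
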