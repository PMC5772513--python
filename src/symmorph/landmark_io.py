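"""Reading, writing and validation of landmark data and its bookkeeping objects.

A dataset is a list of :class:`LandmarkConfiguration` (one per specimen and
digitization replicate), all sharing the same landmark count ``k``, dimension
``d`` and landmark ordering.  Bilateral structure is described by a
:class:`SymmetryMap` (left/right landmark pairs plus unpaired midline
landmarks); modularity hypotheses are :class:`ModulePartition` objects that
assign every landmark to exactly one of at least two modules.

Supported file formats:

* TPS landmark files (``LM=``/``LM3=`` blocks with optional ``ID=`` and
  ``SCALE=`` records; 1-based conventions in files are translated to the
  0-based indices used everywhere in this package),
* long-format CSV with columns ``specimen_id, replicate, landmark_index,
  x, y[, z]``,
* JSON/YAML for symmetry maps and module partitions,
* CSV (``specimen_id, group``) for group labels.

Missing landmarks are rejected, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LandmarkConfiguration",
    "SymmetryMap",
    "ModulePartition",
    "read_tps",
    "write_tps",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "validate_symmetry_map",
    "read_symmetry_map",
    "write_symmetry_map",
    "load_partition",
    "write_partition",
    "read_group_labels",
    "write_group_labels",
    "stack_dataset",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized landmarks: a ``k x d`` coordinate matrix (mm)."""

    specimen_id: str
    coords: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be a k x d matrix, "
                f"got shape {self.coords.shape}"
            )
        if self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"specimen {self.specimen_id!r}: dimension must be 2 or 3, "
                f"got {self.coords.shape[1]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"specimen {self.specimen_id!r}: missing or non-finite "
                "coordinates are not allowed"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class SymmetryMap:
    """Left/right landmark pairing defining the reflect-relabel operator.

    ``pairs`` lists ``(left_index, right_index)`` tuples; ``midline`` lists
    landmarks lying on the symmetry plane; ``reflection_axis`` is the
    coordinate axis whose sign is flipped by a reflection (default: first
    axis).  Pairs and midline must jointly cover ``0..k-1`` with no overlap.
    """

    pairs: list[tuple[int, int]]
    midline: list[int]
    reflection_axis: int = 0

    def __post_init__(self) -> None:
        self.pairs = [(int(a), int(b)) for a, b in self.pairs]
        self.midline = [int(i) for i in self.midline]

    @property
    def k(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    @property
    def k_pairs(self) -> int:
        return len(self.pairs)

    @property
    def k_midline(self) -> int:
        return len(self.midline)

    def permutation(self) -> np.ndarray:
        """Row permutation of the relabeling step: left<->right swapped."""
        perm = np.empty(self.k, dtype=int)
        for left, right in self.pairs:
            perm[left] = right
            perm[right] = left
        for m in self.midline:
            perm[m] = m
        return perm


def validate_symmetry_map(smap: SymmetryMap, k: int) -> SymmetryMap:
    """Check that *smap* covers exactly the landmark set ``0..k-1``.

    Returns the map unchanged; raises ``ValueError`` with a descriptive
    message on overlap, duplication, uncovered or out-of-range indices.
    Idempotent.
    """
    seen: dict[int, str] = {}
    for left, right in smap.pairs:
        if left == right:
            raise ValueError(f"pair ({left}, {right}) maps a landmark to itself")
        for idx in (left, right):
            if idx in seen:
                raise ValueError(f"index {idx} appears twice (in pairs)")
            seen[idx] = "pairs"
    for idx in smap.midline:
        if idx in seen:
            raise ValueError(f"index {idx} in both pairs and midline")
        seen[idx] = "midline"
    for idx in seen:
        if not 0 <= idx < k:
            raise ValueError(f"landmark index {idx} out of range for k={k}")
    for idx in range(k):
        if idx not in seen:
            raise ValueError(f"landmark {idx} unassigned (not in pairs or midline)")
    return smap


@dataclass
class ModulePartition:
    """Named assignment of every landmark to exactly one of >=2 modules."""

    name: str
    assignment: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = {int(k): str(v) for k, v in self.assignment.items()}
        self.validate()

    def validate(self) -> None:
        labels = set(self.assignment.values())
        if len(labels) < 2:
            raise ValueError(
                f"partition {self.name!r} needs >=2 modules, got {len(labels)}"
            )
        for label in labels:
            members = [i for i, m in self.assignment.items() if m == label]
            if len(members) < 2:
                raise ValueError(f"module {label!r} has <2 landmarks")

    @property
    def modules(self) -> list[str]:
        """Module labels in first-appearance order."""
        out: list[str] = []
        for label in self.assignment.values():
            if label not in out:
                out.append(label)
        return out

    def members(self, label: str) -> list[int]:
        return sorted(i for i, m in self.assignment.items() if m == label)

    def labels_array(self, k: int | None = None) -> np.ndarray:
        """Per-landmark module labels as an object array indexed 0..k-1."""
        if k is None:
            k = max(self.assignment) + 1
        arr = np.empty(k, dtype=object)
        for i in range(k):
            if i not in self.assignment:
                raise ValueError(f"partition {self.name!r}: landmark {i} unassigned")
            arr[i] = self.assignment[i]
        return arr


# ---------------------------------------------------------------------------
# TPS files
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Each record starts with ``LM=<n>`` (2D) or ``LM3=<n>`` (3D), followed by
    one coordinate line per landmark and optional ``ID=`` and ``SCALE=``
    records; SCALE multiplies all coordinates of its record.  Landmark counts
    must be homogeneous across records.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if not (upper.startswith("LM=") or upper.startswith("LM3=")):
            raise ValueError(
                f"{path}: line {i + 1}: expected LM=/LM3= block, got {line!r}"
            )
        d = 3 if upper.startswith("LM3=") else 2
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ValueError(
                f"{path}: record {record_index}, line {i + 1}: "
                f"unparseable landmark count in {line!r}"
            ) from exc
        i += 1
        rows = []
        for j in range(n_lm):
            if i >= len(lines):
                raise ValueError(
                    f"{path}: record {record_index}: truncated block "
                    f"({j} of {n_lm} landmarks read)"
                )
            parts = lines[i].split()
            if len(parts) != d:
                raise ValueError(
                    f"{path}: record {record_index}, line {i + 1}: expected "
                    f"{d} coordinates, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: record {record_index}, line {i + 1}: "
                    f"unparseable coordinate in {lines[i]!r}"
                ) from exc
            i += 1
        spec_id = f"record_{record_index}"
        scale = None
        while i < len(lines) and lines[i].strip() and "=" in lines[i] and \
                not lines[i].strip().upper().startswith(("LM=", "LM3=")):
            key, _, value = lines[i].strip().partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: record {record_index}, line {i + 1}: "
                        f"unparseable SCALE {value!r}"
                    ) from exc
            i += 1
        coords = np.asarray(rows, dtype=float)
        if scale is not None:
            coords = coords * scale
        configs.append(LandmarkConfiguration(spec_id, coords))
        record_index += 1
    if not configs:
        raise ValueError(f"{path}: no TPS records found")
    shapes = {c.coords.shape for c in configs}
    if len(shapes) > 1:
        raise ValueError(
            f"{path}: heterogeneous landmark counts across records: "
            f"{sorted(s[0] for s in shapes)}"
        )
    return configs


def write_tps(path: str | Path, configs: Sequence[LandmarkConfiguration]) -> None:
    lines: list[str] = []
    for c in configs:
        tag = "LM3" if c.d == 3 else "LM"
        lines.append(f"{tag}={c.k}")
        for row in c.coords:
            lines.append(" ".join(format(v, ".10g") for v in row))
        lines.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Long-format CSV
# ---------------------------------------------------------------------------

def read_landmarks_csv(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a long-format landmark table.

    Required columns: ``specimen_id, landmark_index, x, y`` (``z`` optional
    for 3D, ``replicate`` optional and defaulting to 1).  Landmark indices
    must run 0..k-1 without gaps within each (specimen, replicate) block.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen_id", "landmark_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    coord_cols = ["x", "y"] + (["z"] if "z" in df.columns else [])

    dup = df.duplicated(subset=["specimen_id", "replicate", "landmark_index"])
    if dup.any():
        keys = df.loc[dup, ["specimen_id", "replicate", "landmark_index"]]
        raise ValueError(
            f"{path}: duplicate (specimen, replicate, landmark) rows: "
            f"{keys.to_records(index=False).tolist()}"
        )

    configs = []
    k_all = df["landmark_index"].max() + 1
    for (sid, rep), block in df.groupby(["specimen_id", "replicate"], sort=True):
        idx = set(block["landmark_index"])
        for j in range(int(k_all)):
            if j not in idx:
                raise ValueError(
                    f"{path}: specimen {sid!r} replicate {rep}: missing landmark {j}"
                )
        block = block.sort_values("landmark_index")
        configs.append(
            LandmarkConfiguration(str(sid), block[coord_cols].to_numpy(float), int(rep))
        )
    if not configs:
        raise ValueError(f"{path}: no landmark rows found")
    return configs


def write_landmarks_csv(path: str | Path, configs: Sequence[LandmarkConfiguration]) -> None:
    rows = []
    for c in configs:
        for j, coord in enumerate(c.coords):
            row = {"specimen_id": c.specimen_id, "replicate": c.replicate,
                   "landmark_index": j, "x": coord[0], "y": coord[1]}
            if c.d == 3:
                row["z"] = coord[2]
            rows.append(row)
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Symmetry maps, partitions and group labels
# ---------------------------------------------------------------------------

def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_symmetry_map(path: str | Path) -> SymmetryMap:
    data = _load_structured(Path(path))
    return SymmetryMap(
        pairs=[tuple(p) for p in data["pairs"]],
        midline=list(data.get("midline", [])),
        reflection_axis=int(data.get("reflection_axis", 0)),
    )


def write_symmetry_map(path: str | Path, smap: SymmetryMap) -> None:
    data = {
        "pairs": [list(p) for p in smap.pairs],
        "midline": list(smap.midline),
        "reflection_axis": smap.reflection_axis,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def load_partition(path: str | Path, name: str | None = None) -> ModulePartition:
    """Load a module partition from a JSON/YAML mapping label -> index list."""
    path = Path(path)
    data = _load_structured(path)
    if "modules" in data:
        name = name or data.get("name", path.stem)
        data = data["modules"]
    assignment: dict[int, str] = {}
    for label, indices in data.items():
        for idx in indices:
            idx = int(idx)
            if idx in assignment:
                raise ValueError(f"landmark {idx} in two modules "
                                 f"({assignment[idx]!r} and {label!r})")
            assignment[idx] = str(label)
    return ModulePartition(name or path.stem, assignment)


def write_partition(path: str | Path, partition: ModulePartition) -> None:
    modules = {label: partition.members(label) for label in partition.modules}
    Path(path).write_text(
        json.dumps({"name": partition.name, "modules": modules}, indent=2) + "\n"
    )


def read_group_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"specimen_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: group labels need columns specimen_id, group")
    return dict(zip(df["specimen_id"], df["group"]))


def write_group_labels(path: str | Path, labels: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"specimen_id": list(labels), "group": list(labels.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset helpers
# ---------------------------------------------------------------------------

def stack_dataset(
    configs: Iterable[LandmarkConfiguration],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Stack configurations into arrays for numerical work.

    Returns ``(specimen_ids, replicates, coords)`` where *specimen_ids* is the
    per-record id list, *replicates* the per-record replicate index and
    *coords* an ``(n_records, k, d)`` array.  Raises on heterogeneous shapes.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("empty dataset")
    shapes = {c.coords.shape for c in configs}
    if len(shapes) > 1:
        raise ValueError(f"heterogeneous landmark counts: {sorted(shapes)}")
    ids = [c.specimen_id for c in configs]
    reps = np.array([c.replicate for c in configs], dtype=int)
    coords = np.stack([c.coords for c in configs])
    return ids, reps, coords
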