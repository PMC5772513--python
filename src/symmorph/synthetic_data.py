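"""Synthetic bilateral landmark datasets with known covariance structure.

The generator emulates the statistical design of a facial-landmark study:
specimens carry

* an among-individual (genetic/environmental) shape deviation applied
  **symmetrically** to both sides, drawn from a modular covariance built by a
  latent-factor model (one factor per module plus one global factor, so the
  matrix is positive semi-definite for any within/between correlation pair),
* a **directional asymmetry** offset plus a specimen-specific fluctuating
  asymmetry draw, both applied antisymmetrically (left gets +, mirrored
  right gets the reflected negative),
* i.i.d. digitization error added per replicate.

Because deviations are applied exactly symmetrically/antisymmetrically to a
perfectly symmetric template, the ground-truth decomposition is exact before
superimposition; any distortion introduced by GPA is measured, not
confounded.  The default scenario mirrors a 3-D face: 34 landmarks (15
bilateral pairs + 4 midline), 500 specimens, a single digitization.

Free parameterization.  A symmetric deviation is determined by the left
landmark of each pair (d coordinates) and the in-plane coordinates of each
midline landmark (d-1); an antisymmetric deviation by the left landmark of
each pair (d) and the off-plane coordinate of each midline landmark (1).
Latent-factor draws happen in these free spaces; linear maps ``L_sym`` and
``L_asym`` expand them to full k x d fields, and the implied full-space
covariances ``L S L'`` are reported as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landmark_io import (
    LandmarkConfiguration,
    ModulePartition,
    SymmetryMap,
    validate_symmetry_map,
)
from .symmetry_gpa import centroid_size, reflect_relabel_array

__all__ = [
    "SyntheticParams",
    "SyntheticDataset",
    "make_template",
    "face_template",
    "face_partitions",
    "generate",
]


# ---------------------------------------------------------------------------
# 34-landmark face template (mm).  x is the left-right axis (reflection
# axis), y vertical, z depth.  Midline landmarks have x = 0 exactly; pairs
# are stored (left, right) with the left side at positive x.
# ---------------------------------------------------------------------------

_FACE_MIDLINE = [
    ("nasion", (0.0, 50.0, 95.0)),
    ("pronasale", (0.0, 20.0, 115.0)),
    ("subnasale", (0.0, 8.0, 100.0)),
    ("gnathion", (0.0, -45.0, 90.0)),
]

_FACE_PAIRS = [
    ("endocanthion", (17.0, 45.0, 90.0)),
    ("exocanthion", (45.0, 45.0, 82.0)),
    ("palpebrale_superius", (31.0, 50.0, 88.0)),
    ("palpebrale_inferius", (31.0, 40.0, 88.0)),
    ("alare", (17.0, 12.0, 98.0)),
    ("alar_crest", (15.0, 5.0, 96.0)),
    ("cheilion", (26.0, -12.0, 92.0)),
    ("crista_philtri", (5.0, -5.0, 103.0)),
    ("tragion", (70.0, 35.0, 25.0)),
    ("otobasion_superius", (72.0, 45.0, 25.0)),
    ("otobasion_inferius", (68.0, 10.0, 28.0)),
    ("preaurale", (65.0, 30.0, 32.0)),
    ("zygion", (65.0, 30.0, 60.0)),
    ("frontotemporale", (52.0, 75.0, 70.0)),
    ("gonion", (55.0, -25.0, 45.0)),
]

# Illustrative module memberships (by landmark name, pairs as units) for the
# four facial modularity hypotheses on this template.
_FACE_HYPOTHESES: dict[str, dict[str, list[str]]] = {
    "functional": {
        "eyes": ["endocanthion", "exocanthion", "palpebrale_superius",
                 "palpebrale_inferius", "nasion", "frontotemporale"],
        "mouth": ["cheilion", "crista_philtri", "gnathion", "gonion"],
        "nose": ["alare", "alar_crest", "pronasale", "subnasale"],
        "ears": ["tragion", "otobasion_superius", "otobasion_inferius",
                 "preaurale", "zygion"],
    },
    "midline": {
        "sagittal": ["nasion", "pronasale", "subnasale", "gnathion"],
        "midsagittal": ["endocanthion", "exocanthion", "palpebrale_superius",
                        "palpebrale_inferius", "alare", "alar_crest",
                        "cheilion", "crista_philtri"],
        "lateral": ["tragion", "otobasion_superius", "otobasion_inferius",
                    "preaurale", "zygion", "frontotemporale", "gonion"],
    },
    "facial_thirds": {
        "middle": ["nasion", "pronasale", "endocanthion", "exocanthion",
                   "palpebrale_superius", "palpebrale_inferius", "alare",
                   "alar_crest", "zygion", "tragion", "preaurale",
                   "otobasion_superius", "frontotemporale"],
        "inferior": ["subnasale", "cheilion", "crista_philtri", "gnathion",
                     "gonion", "otobasion_inferius"],
    },
    "neuro_splanchno": {
        "neurocranium": ["nasion", "frontotemporale", "tragion",
                         "otobasion_superius", "otobasion_inferius",
                         "preaurale"],
        "splanchnocranium": ["pronasale", "subnasale", "gnathion",
                             "endocanthion", "exocanthion",
                             "palpebrale_superius", "palpebrale_inferius",
                             "alare", "alar_crest", "cheilion",
                             "crista_philtri", "zygion", "gonion"],
    },
}


def face_template() -> tuple[np.ndarray, SymmetryMap, list[str]]:
    """The 34-landmark, 3-D face template.

    Returns ``(coords, symmetry_map, landmark_names)``; midline landmarks
    occupy indices 0-3, pairs follow interleaved (left, right).
    """
    k = len(_FACE_MIDLINE) + 2 * len(_FACE_PAIRS)
    coords = np.zeros((k, 3))
    names: list[str] = []
    midline_idx = []
    for i, (name, xyz) in enumerate(_FACE_MIDLINE):
        coords[i] = xyz
        names.append(name)
        midline_idx.append(i)
    pairs = []
    base = len(_FACE_MIDLINE)
    for p, (name, xyz) in enumerate(_FACE_PAIRS):
        left, right = base + 2 * p, base + 2 * p + 1
        coords[left] = xyz
        coords[right] = xyz * np.array([-1.0, 1.0, 1.0])
        names.append(f"{name}_l")
        names.append(f"{name}_r")
        pairs.append((left, right))
    smap = SymmetryMap(pairs=pairs, midline=midline_idx, reflection_axis=0)
    validate_symmetry_map(smap, k)
    return coords, smap, names


def face_partitions() -> dict[str, ModulePartition]:
    """The four example modularity hypotheses on the face template."""
    _, _, names = face_template()
    base = {n.removesuffix("_l").removesuffix("_r"): [] for n in names}
    for idx, n in enumerate(names):
        base[n.removesuffix("_l").removesuffix("_r")].append(idx)
    out = {}
    for hyp, modules in _FACE_HYPOTHESES.items():
        assignment: dict[int, str] = {}
        for label, members in modules.items():
            for landmark_name in members:
                for idx in base[landmark_name]:
                    assignment[idx] = label
        out[hyp] = ModulePartition(hyp, assignment)
    return out


def make_template(
    k_pairs: int, k_midline: int, d: int, seed: int | None = None,
    spread: float = 50.0,
) -> tuple[np.ndarray, SymmetryMap]:
    """Random but reproducible symmetric template.

    Midline landmarks have the reflection-axis coordinate exactly 0; pairs
    are exact mirror images.  Requires ``k_pairs >= 1`` or ``k_midline >= 3``
    so the template is non-degenerate.
    """
    if k_pairs < 1 and k_midline < 3:
        raise ValueError("degenerate template: need k_pairs >= 1 or k_midline >= 3")
    rng = np.random.default_rng(seed)
    k = 2 * k_pairs + k_midline
    coords = np.zeros((k, d))
    midline = list(range(k_midline))
    for m in midline:
        coords[m] = rng.uniform(-spread, spread, d)
        coords[m, 0] = 0.0
    pairs = []
    base = k_midline
    refl = np.ones(d)
    refl[0] = -1.0
    for p in range(k_pairs):
        left, right = base + 2 * p, base + 2 * p + 1
        xyz = rng.uniform(-spread, spread, d)
        xyz[0] = rng.uniform(0.2 * spread, spread)   # keep sides separated
        coords[left] = xyz
        coords[right] = xyz * refl
        pairs.append((left, right))
    smap = SymmetryMap(pairs=pairs, midline=midline, reflection_axis=0)
    if centroid_size(coords) <= 0:
        raise ValueError("degenerate template: centroid size 0")
    return coords, smap


# ---------------------------------------------------------------------------
# Parameters and dataset containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticParams:
    """Study-design parameters of the generator.

    SDs are in template units (mm).  ``fa_structure`` selects the FA
    covariance: ``"proportional"`` reuses the individual-level modular
    structure scaled by ``(sigma_fa / sigma_ind)^2``; ``"independent"``
    draws an unrelated random covariance; ``"isotropic"`` is white noise.
    """

    n_specimens: int = 500
    k_pairs: int = 15
    k_midline: int = 4
    d: int = 3
    rho_within: float = 0.6
    rho_between: float = 0.1
    sigma_ind: float = 1.0
    da_magnitude: float = 0.4
    sigma_fa: float = 0.35
    fa_structure: str = "proportional"
    sigma_err: float = 0.0
    n_replicates: int = 1
    group_effects: dict[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rho_within < self.rho_between:
            raise ValueError("modular scenarios require rho_within >= rho_between")
        if not 0 <= self.rho_between <= self.rho_within <= 1:
            raise ValueError("correlations must satisfy 0 <= rho_between <= rho_within <= 1")
        for name in ("sigma_ind", "sigma_fa", "sigma_err", "da_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fa_structure not in ("proportional", "independent", "isotropic"):
            raise ValueError(f"unknown fa_structure {self.fa_structure!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated configurations plus the ground truth that produced them."""

    configurations: list[LandmarkConfiguration]
    smap: SymmetryMap
    partition: ModulePartition
    group_labels: dict[str, str] | None
    template: np.ndarray
    params: SyntheticParams
    sigma_ind_full: np.ndarray       # (kd, kd) implied symmetric-field covariance
    sigma_fa_full: np.ndarray        # (kd, kd) implied FA-field covariance
    da_field: np.ndarray             # (k, d) antisymmetric DA offset
    group_shift_fields: dict[str, np.ndarray] = field(default_factory=dict)
    sym_dev: np.ndarray | None = None    # (n, k, d) true symmetric deviations
    asym_dev: np.ndarray | None = None   # (n, k, d) true asymmetric deviations

    @property
    def specimen_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.configurations:
            if c.specimen_id not in seen:
                seen.append(c.specimen_id)
        return seen


# ---------------------------------------------------------------------------
# Free-space machinery
# ---------------------------------------------------------------------------

def _free_maps(smap: SymmetryMap, d: int) -> tuple[np.ndarray, np.ndarray,
                                                   list[int], list[int]]:
    """Linear maps from free parameters to full antisymmetric/symmetric fields.

    Returns ``(L_sym, L_asym, sym_landmarks, asym_landmarks)`` where the
    landmark lists give, per free variable, the landmark owning it (used for
    module labels).
    """
    k = smap.k
    axis = smap.reflection_axis
    refl = np.ones(d)
    refl[axis] = -1.0

    sym_cols: list[np.ndarray] = []
    sym_landmarks: list[int] = []
    asym_cols: list[np.ndarray] = []
    asym_landmarks: list[int] = []

    def unit(landmark: int, coord: int, value: float = 1.0) -> np.ndarray:
        col = np.zeros(k * d)
        col[landmark * d + coord] = value
        return col

    for left, right in smap.pairs:
        for c in range(d):
            sym_cols.append(unit(left, c) + unit(right, c, refl[c]))
            sym_landmarks.append(left)
            asym_cols.append(unit(left, c) + unit(right, c, -refl[c]))
            asym_landmarks.append(left)
    for m in smap.midline:
        for c in range(d):
            if c == axis:
                asym_cols.append(unit(m, c))
                asym_landmarks.append(m)
            else:
                sym_cols.append(unit(m, c))
                sym_landmarks.append(m)
    return (np.column_stack(sym_cols), np.column_stack(asym_cols),
            sym_landmarks, asym_landmarks)


def _factor_cov(labels: Sequence[str], rho_w: float, rho_b: float,
                sigma: float) -> np.ndarray:
    """Covariance implied by the one-factor-per-module latent model."""
    labels = np.asarray(labels, object)
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, rho_w, rho_b)
    np.fill_diagonal(corr, 1.0)
    return sigma ** 2 * corr


def _factor_draws(rng: np.random.Generator, n: int, labels: Sequence[str],
                  rho_w: float, rho_b: float, sigma: float) -> np.ndarray:
    """Draw n rows from the latent-factor model over the labelled variables."""
    labels = np.asarray(labels, object)
    nv = labels.size
    modules = list(dict.fromkeys(labels))
    g = rng.standard_normal((n, 1))
    f = rng.standard_normal((n, len(modules)))
    e = rng.standard_normal((n, nv))
    module_idx = np.array([modules.index(l) for l in labels])
    x = (np.sqrt(rho_b) * g
         + np.sqrt(rho_w - rho_b) * f[:, module_idx]
         + np.sqrt(1.0 - rho_w) * e)
    return sigma * x


def _random_cov(rng: np.random.Generator, nv: int, sigma: float) -> np.ndarray:
    """Random Wishart-style covariance, scaled to mean variance sigma^2."""
    a = rng.standard_normal((nv, nv + 5))
    S = a @ a.T
    return S * (sigma ** 2 / np.mean(np.diag(S)))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _default_partition(smap: SymmetryMap) -> ModulePartition:
    """Two-module split for generic templates: first half of pairs + midline
    against the rest (pair partners share a module)."""
    assignment: dict[int, str] = {}
    half = max(1, smap.k_pairs // 2)
    for p, (left, right) in enumerate(smap.pairs):
        label = "module_a" if p < half else "module_b"
        assignment[left] = label
        assignment[right] = label
    for m in smap.midline:
        assignment[m] = "module_b" if smap.k_pairs > 1 else "module_a"
    return ModulePartition("true_partition", assignment)


def generate(params: SyntheticParams,
             partition: ModulePartition | None = None) -> SyntheticDataset:
    """Generate a bilateral landmark dataset under *params*.

    All randomness flows from one generator seeded by ``params.seed``; the
    same seed yields a bit-identical dataset.
    """
    rng = np.random.default_rng(params.seed)
    k_expected = 2 * params.k_pairs + params.k_midline

    if (params.k_pairs, params.k_midline, params.d) == (15, 4, 3):
        template, smap, _ = face_template()
        if partition is None:
            partition = face_partitions()["functional"]
    else:
        template, smap = make_template(
            params.k_pairs, params.k_midline, params.d,
            seed=int(rng.integers(2 ** 31)),
        )
        if partition is None:
            partition = _default_partition(smap)
    k, d = template.shape
    assert k == k_expected
    partition.labels_array(k)   # every landmark assigned

    L_sym, L_asym, sym_lm, asym_lm = _free_maps(smap, d)
    lm_labels = partition.labels_array(k)
    sym_labels = [lm_labels[l] for l in sym_lm]
    asym_labels = [lm_labels[l] for l in asym_lm]
    n_sym, n_asym = len(sym_labels), len(asym_labels)

    # --- individual (symmetric) structure
    cov_sym_free = _factor_cov(sym_labels, params.rho_within,
                               params.rho_between, params.sigma_ind)
    sym_free = _factor_draws(rng, params.n_specimens, sym_labels,
                             params.rho_within, params.rho_between,
                             params.sigma_ind)

    # --- FA structure
    if params.fa_structure == "proportional":
        cov_asym_free = _factor_cov(asym_labels, params.rho_within,
                                    params.rho_between, params.sigma_fa)
        fa_free = _factor_draws(rng, params.n_specimens, asym_labels,
                                params.rho_within, params.rho_between,
                                params.sigma_fa)
    elif params.fa_structure == "independent":
        cov_asym_free = _random_cov(rng, n_asym, params.sigma_fa)
        chol = np.linalg.cholesky(cov_asym_free + 1e-12 * np.eye(n_asym))
        fa_free = rng.standard_normal((params.n_specimens, n_asym)) @ chol.T
    else:  # isotropic
        cov_asym_free = params.sigma_fa ** 2 * np.eye(n_asym)
        fa_free = params.sigma_fa * rng.standard_normal(
            (params.n_specimens, n_asym))

    # --- directional asymmetry: fixed random direction, stated magnitude
    da_free = np.zeros(n_asym)
    if params.da_magnitude > 0:
        direction = rng.standard_normal(n_asym)
        da_free = params.da_magnitude * direction / np.linalg.norm(direction)
    da_field = (L_asym @ da_free).reshape(k, d)

    # --- group shifts (symmetric-type fields)
    group_labels: dict[str, str] | None = None
    group_shift_fields: dict[str, np.ndarray] = {}
    ids = [f"spec_{i:04d}" for i in range(params.n_specimens)]
    shift_per_spec = np.zeros((params.n_specimens, k, d))
    if params.group_effects:
        groups = list(params.group_effects)
        group_labels = {sid: groups[i % len(groups)] for i, sid in enumerate(ids)}
        for g in groups:
            direction = rng.standard_normal(n_sym)
            shift_free = params.group_effects[g] * direction / np.linalg.norm(direction)
            group_shift_fields[g] = (L_sym @ shift_free).reshape(k, d)
        for i, sid in enumerate(ids):
            shift_per_spec[i] = group_shift_fields[group_labels[sid]]

    sym_dev = (sym_free @ L_sym.T).reshape(params.n_specimens, k, d) + shift_per_spec
    asym_dev = (fa_free @ L_asym.T).reshape(params.n_specimens, k, d) + da_field

    configs: list[LandmarkConfiguration] = []
    for i, sid in enumerate(ids):
        true_shape = template + sym_dev[i] + asym_dev[i]
        for rep in range(1, params.n_replicates + 1):
            noisy = true_shape
            if params.sigma_err > 0:
                noisy = true_shape + rng.normal(0.0, params.sigma_err, (k, d))
            configs.append(LandmarkConfiguration(sid, noisy, rep))

    assert np.allclose(reflect_relabel_array(template, smap), template)
    return SyntheticDataset(
        configurations=configs,
        smap=smap,
        partition=partition,
        group_labels=group_labels,
        template=template,
        params=params,
        sigma_ind_full=L_sym @ cov_sym_free @ L_sym.T,
        sigma_fa_full=L_asym @ cov_asym_free @ L_asym.T,
        da_field=da_field,
        group_shift_fields=group_shift_fields,
        sym_dev=sym_dev,
        asym_dev=asym_dev,
    )
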