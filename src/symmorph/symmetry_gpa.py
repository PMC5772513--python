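"""Generalized Procrustes analysis with object symmetry.

For bilaterally symmetric structures where the symmetry axis runs through the
object itself (a face, a skull), asymmetry is internal to each configuration.
The analysis duplicates every configuration as its reflected and relabeled
copy, superimposes originals and copies jointly, and splits each specimen's
shape into

* a **symmetric component** — the average of the aligned original and its
  aligned reflected copy, carrying among-individual variation, and
* an **asymmetric component** — half their difference; its sample mean is
  directional asymmetry (DA) and the deviations around that mean are
  fluctuating asymmetry (FA).

With the half-difference convention, ``symmetric + asymmetric`` reconstructs
the aligned configuration exactly.

The consensus of the doubled sample is symmetric only up to an arbitrary
rotation of the common frame; :func:`decompose_symmetry` therefore rotates the
whole aligned sample into the frame in which the consensus is exactly
reflection-symmetric (midline landmarks on the symmetry plane) before
computing components, so the symmetric component is invariant under
reflect-relabel to machine precision.

A Procrustes ANOVA partitions the squared Procrustes variation of the doubled
dataset into individual, side (DA), individual x side (FA) and, when several
digitization replicates exist, measurement-error effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landmark_io import (
    LandmarkConfiguration,
    SymmetryMap,
    stack_dataset,
    validate_symmetry_map,
)

__all__ = [
    "AlignedSample",
    "SymmetryDecomposition",
    "ProcrustesANOVATable",
    "reflect_relabel",
    "reflect_relabel_array",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "decompose_symmetry",
    "procrustes_anova",
    "shape_space_dims",
]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def centroid_size(coords: np.ndarray) -> np.ndarray:
    """Square root of summed squared landmark distances from the centroid.

    Works on a single ``(k, d)`` configuration or a stacked ``(n, k, d)``
    array (returning a length-n vector).
    """
    coords = np.asarray(coords, float)
    centered = coords - coords.mean(axis=-2, keepdims=True)
    return np.sqrt((centered ** 2).sum(axis=(-2, -1)))


def reflect_relabel_array(coords: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    """Reflect on ``smap.reflection_axis`` and swap paired landmark rows.

    Accepts ``(k, d)`` or ``(n, k, d)`` arrays.  An involution: applying it
    twice returns the input exactly.
    """
    coords = np.asarray(coords, float)
    out = coords.copy()
    out[..., smap.reflection_axis] *= -1.0
    perm = smap.permutation()
    return out[..., perm, :]


def reflect_relabel(config: LandmarkConfiguration, smap: SymmetryMap) -> LandmarkConfiguration:
    """Reflect-relabel operator on a single configuration."""
    validate_symmetry_map(smap, config.k)
    if smap.reflection_axis >= config.d:
        raise ValueError(
            f"reflection_axis {smap.reflection_axis} >= dimension {config.d}"
        )
    return LandmarkConfiguration(
        config.specimen_id,
        reflect_relabel_array(config.coords, smap),
        config.replicate,
    )


def _optimal_rotations(stack: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotations R_i minimizing ||X_i R_i - target|| (batched Kabsch)."""
    H = np.einsum("nkd,ke->nde", stack, target)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nde,nef->ndf", U, Vt))
    d = stack.shape[-1]
    signs = np.ones((stack.shape[0], d))
    signs[:, -1] = np.sign(det)
    signs[signs == 0] = 1.0
    return np.einsum("nde,ne,nef->ndf", U, signs, Vt)


def _rotate(stack: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    return np.einsum("nkd,nde->nke", stack, rotations)


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------

@dataclass
class AlignedSample:
    """Result of a generalized Procrustes superimposition."""

    aligned: np.ndarray           # (n, k, d), centered, unit size if scaled
    consensus: np.ndarray         # (k, d) mean shape
    centroid_sizes: np.ndarray    # (n,) original sizes (mm)
    n_iterations: int
    converged: bool


def gpa(
    configs: Sequence[np.ndarray] | np.ndarray,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    names: Sequence[str] | None = None,
) -> AlignedSample:
    """Iterative generalized Procrustes superimposition.

    Each configuration is centered at the origin and (optionally) scaled to
    unit centroid size, then repeatedly rotated to the running consensus by
    orthogonal Procrustes until the consensus moves less than *tol* (root
    summed squared difference) or *max_iter* is reached.  The consensus is
    initialized from the arithmetic mean of the centered, scaled
    configurations, which makes the result independent of specimen order.
    """
    stack = np.stack([np.asarray(c, float) for c in configs])
    n, k, d = stack.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")

    sizes = centroid_size(stack)
    for i, s in enumerate(sizes):
        if s <= 0 or not np.isfinite(s):
            name = names[i] if names is not None else f"index {i}"
            raise ValueError(f"degenerate configuration (centroid size 0): {name}")

    stack = stack - stack.mean(axis=1, keepdims=True)
    if scale:
        stack = stack / sizes[:, None, None]

    consensus = stack.mean(axis=0)
    if centroid_size(consensus) < 1e-6:
        # mean of arbitrarily oriented shapes can collapse; restart from one shape
        consensus = stack[0]

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = _rotate(stack, _optimal_rotations(stack, consensus))
        new_consensus = aligned.mean(axis=0)
        if scale:
            new_consensus = new_consensus / centroid_size(new_consensus)
        delta = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        stack = aligned
        if delta < tol:
            converged = True
            break
    # final pass so every configuration is optimally rotated to the final mean
    aligned = _rotate(stack, _optimal_rotations(stack, consensus))
    return AlignedSample(aligned, aligned.mean(axis=0), sizes, iterations, converged)


def procrustes_distance(a: np.ndarray, b: np.ndarray, scale: bool = True) -> float:
    """Partial Procrustes distance between two configurations.

    Centers both, optionally scales to unit centroid size, rotates *b* onto
    *a* optimally and returns the root summed squared difference.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if scale:
        a = a / centroid_size(a)
        b = b / centroid_size(b)
    rot = _optimal_rotations(b[None], a)[0]
    return float(np.sqrt(((b @ rot - a) ** 2).sum()))


# ---------------------------------------------------------------------------
# Symmetric frame
# ---------------------------------------------------------------------------

def _symmetrize_frame(aligned: np.ndarray, consensus: np.ndarray,
                      smap: SymmetryMap) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the aligned sample so the consensus is reflection-symmetric.

    The GPA consensus C of a doubled (original + reflected-copy) sample
    satisfies ``T(C) = C Q0'`` for some rotation Q0, where T is
    reflect-relabel.  Writing ``U = Q0' R`` (R the coordinate reflection),
    U is an orthogonal symmetric involution; the rotation V whose columns are
    the eigenvectors of U arranged so that ``V R V' = U`` maps the sample
    into the frame where ``T(CV) = CV`` — the symmetry plane coincides with a
    coordinate plane.
    """
    d = consensus.shape[1]
    axis = smap.reflection_axis
    reflected = reflect_relabel_array(consensus, smap)
    q0 = _optimal_rotations(reflected[None], consensus)[0]   # T(C) q0 ~ C
    refl = np.eye(d)
    refl[axis, axis] = -1.0
    u = q0.T @ refl
    u = 0.5 * (u + u.T)  # exact involutions are symmetric; clean numerics
    evals, evecs = np.linalg.eigh(u)
    order = np.argsort(evals)          # single -1 eigenvalue first
    neg = evecs[:, order[0]]
    pos = evecs[:, order[1:]]
    v = np.empty((d, d))
    v[:, axis] = neg
    other = [c for c in range(d) if c != axis]
    for col, vec in zip(other, pos.T):
        v[:, col] = vec
    if np.linalg.det(v) < 0:
        v[:, other[0]] *= -1.0
    rotated = np.einsum("nkd,de->nke", aligned, v)
    cons = rotated.mean(axis=0)
    # enforce exact symmetry of the consensus, then realign everything to it
    cons = 0.5 * (cons + reflect_relabel_array(cons, smap))
    rotated = _rotate(rotated, _optimal_rotations(rotated, cons))
    cons = rotated.mean(axis=0)

    # The frame is still free up to rotations within the symmetry plane (the
    # +1 eigenspace of U is degenerate, so the basis above is arbitrary).
    # Pin it: rotate in-plane coordinates onto the principal axes of the
    # consensus, fix in-plane signs by the largest-magnitude entry, and give
    # the reflection axis the sign that keeps the transform proper.  Any such
    # transform commutes with the coordinate reflection, so the consensus
    # stays exactly symmetric.
    other = [c for c in range(d) if c != axis]
    w = np.zeros((d, d))
    if len(other) == 2:
        m = cons[:, other]
        _, evecs2 = np.linalg.eigh(m.T @ m)
        e = evecs2[:, ::-1]                    # descending variance
        for col in range(2):
            proj = m @ e[:, col]
            if proj[np.argmax(np.abs(proj))] < 0:
                e[:, col] *= -1.0
        w[np.ix_(other, other)] = e
        w[axis, axis] = np.sign(np.linalg.det(w[np.ix_(other, other)]))
    else:                                      # d == 2: only signs to fix
        col = cons[:, other[0]]
        s = 1.0 if col[np.argmax(np.abs(col))] >= 0 else -1.0
        w[other[0], other[0]] = s
        w[axis, axis] = s                      # keep det(w) = +1
    rotated = np.einsum("nkd,de->nke", rotated, w)
    return rotated, rotated.mean(axis=0)


# ---------------------------------------------------------------------------
# Symmetry decomposition
# ---------------------------------------------------------------------------

@dataclass
class SymmetryDecomposition:
    """Symmetric/asymmetric split of every specimen's aligned shape."""

    specimen_ids: list[str]
    symmetric: np.ndarray          # (n, k, d) replicate-averaged
    asymmetric: np.ndarray         # (n, k, d) replicate-averaged
    da_mean: np.ndarray            # (k, d) directional asymmetry
    consensus: np.ndarray          # (k, d)
    centroid_sizes: np.ndarray     # (n,) per-specimen mean original size
    smap: SymmetryMap
    n_replicates: int = 1
    remove_da: bool = True
    # per-replicate components, (n, r, k, d); None with a single replicate
    symmetric_by_rep: np.ndarray | None = field(default=None, repr=False)
    asymmetric_by_rep: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.symmetric.shape[0]

    @property
    def k(self) -> int:
        return self.symmetric.shape[1]

    @property
    def d(self) -> int:
        return self.symmetric.shape[2]

    @property
    def fa(self) -> np.ndarray:
        """Fluctuating-asymmetry deviations (DA removed unless disabled)."""
        if self.remove_da:
            return self.asymmetric - self.da_mean
        return self.asymmetric

    def flat(self, which: str) -> np.ndarray:
        """Flattened (n, k*d) rows of a component: 'symmetric'|'asymmetric'|'fa'."""
        arr = {"symmetric": self.symmetric,
               "asymmetric": self.asymmetric,
               "fa": self.fa}[which]
        return arr.reshape(self.n, -1)


def decompose_symmetry(
    configs: Sequence[LandmarkConfiguration],
    smap: SymmetryMap,
    scale: bool = True,
    align: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    remove_da: bool = True,
) -> tuple[AlignedSample, SymmetryDecomposition]:
    """Joint GPA of originals and reflected copies, then symmetric/asymmetric split.

    The dataset is doubled with reflect-relabel copies, superimposed jointly
    (originals and copies of all replicates together), rotated into the
    symmetric frame, and split per specimen and replicate into

    ``symmetric = (aligned original + aligned reflected copy) / 2``
    ``asymmetric = (aligned original - aligned reflected copy) / 2``

    then averaged over replicates.  ``da_mean`` is the specimen mean of the
    asymmetric components.  With ``align=False`` the configurations are used
    as given (useful for pre-aligned toy data); reflection copies are still
    taken.
    """
    ids, reps, stack = stack_dataset(configs)
    n_records, k, d = stack.shape
    validate_symmetry_map(smap, k)
    if smap.reflection_axis >= d:
        raise ValueError(f"reflection_axis {smap.reflection_axis} >= dimension {d}")

    order: dict[str, dict[int, int]] = {}
    for idx, (sid, rep) in enumerate(zip(ids, reps)):
        order.setdefault(sid, {})
        if rep in order[sid]:
            raise ValueError(f"duplicate replicate {rep} for specimen {sid!r}")
        order[sid][rep] = idx
    rep_counts = {sid: len(r) for sid, r in order.items()}
    n_rep = max(rep_counts.values())
    if len(set(rep_counts.values())) > 1:
        raise ValueError(f"unbalanced replicates per specimen: {rep_counts}")
    specimen_ids = list(order)
    n = len(specimen_ids)

    reflected = reflect_relabel_array(stack, smap)
    doubled = np.concatenate([stack, reflected])

    if align:
        sample = gpa(doubled, scale=scale, tol=tol, max_iter=max_iter,
                     names=[f"{sid} (rep {rep})" for sid, rep in zip(ids, reps)] * 2)
        aligned, consensus = _symmetrize_frame(sample.aligned, sample.consensus, smap)
        sample = AlignedSample(aligned, consensus, sample.centroid_sizes,
                               sample.n_iterations, sample.converged)
    else:
        sample = AlignedSample(doubled, doubled.mean(axis=0),
                               centroid_size(doubled), 0, True)

    originals = sample.aligned[:n_records]
    copies = sample.aligned[n_records:]
    sym_rec = 0.5 * (originals + copies)
    asym_rec = 0.5 * (originals - copies)

    sym_by_rep = np.empty((n, n_rep, k, d))
    asym_by_rep = np.empty((n, n_rep, k, d))
    sizes = np.empty(n)
    for i, sid in enumerate(specimen_ids):
        rec_idx = [order[sid][rep] for rep in sorted(order[sid])]
        sym_by_rep[i] = sym_rec[rec_idx]
        asym_by_rep[i] = asym_rec[rec_idx]
        sizes[i] = sample.centroid_sizes[rec_idx].mean()

    symmetric = sym_by_rep.mean(axis=1)
    asymmetric = asym_by_rep.mean(axis=1)
    decomp = SymmetryDecomposition(
        specimen_ids=specimen_ids,
        symmetric=symmetric,
        asymmetric=asymmetric,
        da_mean=asymmetric.mean(axis=0),
        consensus=sample.consensus,
        centroid_sizes=sizes,
        smap=smap,
        n_replicates=n_rep,
        remove_da=remove_da,
        symmetric_by_rep=sym_by_rep if n_rep > 1 else None,
        asymmetric_by_rep=asym_by_rep if n_rep > 1 else None,
    )
    return sample, decomp


# ---------------------------------------------------------------------------
# Procrustes ANOVA
# ---------------------------------------------------------------------------

def shape_space_dims(k_pairs: int, k_midline: int, d: int) -> tuple[int, int]:
    """Dimensions (s_sym, s_asym) of the symmetric/asymmetric shape subspaces.

    Counted as free coordinates of a symmetric (one representative per pair,
    in-plane midline coordinates) or antisymmetric configuration, minus the
    similarity transformations that preserve that structure:

    * d=3: s_sym = 3p + 2q - 4, s_asym = 3p + q - 3
    * d=2: s_sym = 2p + q - 2,  s_asym = 2p + q - 2

    which sum to the full shape-space dimension (dk - d(d+1)/2 - 1) of the
    doubled configuration.
    """
    p, q = k_pairs, k_midline
    if d == 3:
        return 3 * p + 2 * q - 4, 3 * p + q - 3
    if d == 2:
        return 2 * p + q - 2, 2 * p + q - 2
    raise ValueError(f"dimension must be 2 or 3, got {d}")


@dataclass
class ProcrustesANOVATable:
    """Sums of squares of the object-symmetry Procrustes ANOVA.

    SS are summed over the doubled dataset (original + reflected copy), in
    squared Procrustes units.  ``error`` rows exist only with >=2 replicates.
    """

    effects: list[str]
    ss: dict[str, float]
    df: dict[str, int]
    s_sym: int
    s_asym: int
    n_specimens: int
    n_replicates: int

    @property
    def ms(self) -> dict[str, float]:
        return {e: self.ss[e] / self.df[e] if self.df[e] > 0 else float("nan")
                for e in self.effects}

    @property
    def total_ss(self) -> float:
        return sum(self.ss[e] for e in self.effects)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            {"effect": self.effects,
             "SS": [self.ss[e] for e in self.effects],
             "df": [self.df[e] for e in self.effects],
             "MS": [self.ms[e] for e in self.effects]}
        )


def procrustes_anova(decomp: SymmetryDecomposition) -> ProcrustesANOVATable:
    """Partition the doubled-sample Procrustes SS into symmetry effects.

    With per-(specimen, replicate) symmetric parts ``s_it`` and asymmetric
    parts ``a_it`` (grand symmetric mean ``s_bar``, mean asymmetry ``a_bar``),
    and r replicates:

    * individual:        ``2 r * sum_i ||s_i. - s_bar||^2``
    * side (DA):         ``2 r n * ||a_bar||^2``
    * individual x side: ``2 r * sum_i ||a_i. - a_bar||^2``
    * error (r >= 2):    ``2 * sum_it (||s_it - s_i.||^2 + ||a_it - a_i.||^2)``

    These add up exactly to the total squared deviation of all 2 n r aligned
    configurations around the consensus.  Degrees of freedom follow the
    object-symmetry scheme: individual ``(n-1) s_sym``, side ``s_asym``,
    individual x side ``(n-1) s_asym``, error ``n (r-1)(s_sym + s_asym)``.
    """
    n = decomp.n
    r = decomp.n_replicates
    s_sym, s_asym = shape_space_dims(decomp.smap.k_pairs, decomp.smap.k_midline,
                                     decomp.d)
    sym_mean = decomp.symmetric.mean(axis=0)
    ss_ind = 2.0 * r * float(((decomp.symmetric - sym_mean) ** 2).sum())
    ss_side = 2.0 * r * n * float((decomp.da_mean ** 2).sum())
    ss_is = 2.0 * r * float(((decomp.asymmetric - decomp.da_mean) ** 2).sum())

    effects = ["individual", "side", "individual_x_side"]
    ss = {"individual": ss_ind, "side": ss_side, "individual_x_side": ss_is}
    df = {"individual": (n - 1) * s_sym,
          "side": s_asym,
          "individual_x_side": (n - 1) * s_asym}

    if r >= 2:
        assert decomp.symmetric_by_rep is not None
        sym_dev = decomp.symmetric_by_rep - decomp.symmetric[:, None]
        asym_dev = decomp.asymmetric_by_rep - decomp.asymmetric[:, None]
        ss["error"] = 2.0 * float((sym_dev ** 2).sum() + (asym_dev ** 2).sum())
        df["error"] = n * (r - 1) * (s_sym + s_asym)
        effects.append("error")

    return ProcrustesANOVATable(effects, ss, df, s_sym, s_asym, n, r)
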