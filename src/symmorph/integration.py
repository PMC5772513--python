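"""Covariance-matrix similarity and eigenvalue-variance integration metrics.

Two families of analyses live here.

**Matrix similarity.**  The covariance matrices of individual (symmetric)
variation, fluctuating asymmetry and digitization error are compared with
matrix correlations — the Pearson correlation between corresponding
elements — and tested against the null of complete dissimilarity by jointly
permuting the landmark blocks (d x d) of one matrix.  Because the symmetric
and asymmetric components occupy orthogonal, complementary subspaces of the
full landmark space, full-space Ind x FA correlations are structurally
bounded well below one even under perfectly proportional variation; for
proportionality checks the comparison should be restricted to a common
parameterization such as the one-side paired-landmark sub-block
(:func:`landmark_subblock`).

**Integration.**  Morphological integration of a landmark module is measured
from the eigenvalues of its covariance sub-block: with p variables, trace
(total variance) ``tvc`` and mean eigenvalue ``lam = tvc / p``,

* eigenvalue variance      ``ev_var   = sum (lam_i - lam)^2 / p``
* scaled by total variance ``evstv    = ev_var / tvc^2``
* relative (per-variable)  ``evstvnv  = ev_var / (lam^2 (p - 1))``, in [0, 1]

A strongly integrated module concentrates variance in few dimensions (large
eigenvalue variance); evstvnv is 1 for a rank-one module and 0 when all
eigenvalues are equal.  Two ordinary least-squares regressions summarize the
module-level pattern: integration (evstv) on total variance (tvc), and FA
magnitude (trace of the module FA covariance) on integration, each with a
pointwise confidence band for flagging modules with more variation than
their integration predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landmark_io import ModulePartition
from .modularity import component_covariance, landmark_variable_indices
from .symmetry_gpa import SymmetryDecomposition

__all__ = [
    "CovarianceMatrixSet",
    "MatrixCorrelationResult",
    "RegressionResult",
    "build_covariance_set",
    "matrix_correlation",
    "matrix_permutation_test",
    "landmark_subblock",
    "integration_metrics",
    "integration_table",
    "regress",
    "integration_regressions",
]


# ---------------------------------------------------------------------------
# Covariance matrices of the decomposition
# ---------------------------------------------------------------------------

@dataclass
class CovarianceMatrixSet:
    """Individual / FA / error covariance matrices (kd x kd)."""

    individual: np.ndarray
    fa: np.ndarray
    error: np.ndarray | None = None

    def matrices(self) -> dict[str, np.ndarray]:
        out = {"individual": self.individual, "fa": self.fa}
        if self.error is not None:
            out["error"] = self.error
        return out


def build_covariance_set(decomp: SymmetryDecomposition) -> CovarianceMatrixSet:
    """Covariance matrices of the symmetry decomposition.

    * ``individual`` — covariance of the flattened symmetric components,
    * ``fa`` — covariance of the FA deviations (asymmetric minus directional
      asymmetry, unless DA removal was disabled on the decomposition),
    * ``error`` — covariance of per-replicate deviations of the aligned
      configurations around their specimen mean; ``None`` with a single
      digitization.
    """
    individual = component_covariance(decomp.flat("symmetric"))
    fa = component_covariance(decomp.flat("fa"))
    error = None
    if decomp.n_replicates > 1:
        assert decomp.symmetric_by_rep is not None
        n, r = decomp.n, decomp.n_replicates
        # aligned original = symmetric + asymmetric, per replicate
        aligned = decomp.symmetric_by_rep + decomp.asymmetric_by_rep
        dev = aligned - aligned.mean(axis=1, keepdims=True)
        rows = dev.reshape(n * r, -1)
        error = rows.T @ rows / (n * (r - 1))
    return CovarianceMatrixSet(individual, fa, error)


# ---------------------------------------------------------------------------
# Matrix correlation & permutation test
# ---------------------------------------------------------------------------

def _tri_elements(S: np.ndarray, include_diagonal: bool) -> np.ndarray:
    idx = np.tril_indices(S.shape[0], k=0 if include_diagonal else -1)
    return S[idx]


def matrix_correlation(S1: np.ndarray, S2: np.ndarray,
                       include_diagonal: bool = True) -> float:
    """Pearson correlation over lower-triangle elements of two matrices."""
    S1 = np.asarray(S1, float)
    S2 = np.asarray(S2, float)
    if S1.shape != S2.shape or S1.ndim != 2 or S1.shape[0] != S1.shape[1]:
        raise ValueError(f"incompatible shapes {S1.shape} vs {S2.shape}")
    a = _tri_elements(S1, include_diagonal)
    b = _tri_elements(S2, include_diagonal)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant matrix: correlation undefined")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def landmark_subblock(S: np.ndarray, landmarks, d: int) -> np.ndarray:
    """Sub-block of a kd x kd covariance for a subset of landmarks."""
    idx = landmark_variable_indices(np.asarray(landmarks, int), d)
    return S[np.ix_(idx, idx)]


@dataclass
class MatrixCorrelationResult:
    r: float
    p_value: float
    n_perm: int
    include_diagonal: bool
    seed: int | None
    perm_values: np.ndarray


def matrix_permutation_test(
    S1: np.ndarray,
    S2: np.ndarray,
    d: int,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    include_diagonal: bool = True,
) -> MatrixCorrelationResult:
    """Permutation test of a matrix correlation.

    Each permutation draws a random relabeling of the k landmarks and applies
    it to the rows AND columns of *S2* (d x d blocks move jointly), then
    recomputes the correlation with *S1*.  The p-value is
    ``(1 + #{perm r >= observed r}) / (n_perm + 1)``.
    """
    S1 = np.asarray(S1, float)
    S2 = np.asarray(S2, float)
    if S1.shape != S2.shape:
        raise ValueError(f"incompatible shapes {S1.shape} vs {S2.shape}")
    p = S1.shape[0]
    if p % d:
        raise ValueError(f"matrix size {p} not a multiple of d={d}")
    k = p // d
    if k < 3:
        raise ValueError(f"need at least 3 landmarks for permutation, got {k}")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")

    observed = matrix_correlation(S1, S2, include_diagonal)
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed
    perm_values = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(k)
        idx = landmark_variable_indices(perm, d)
        perm_values[b] = matrix_correlation(S1, S2[np.ix_(idx, idx)],
                                            include_diagonal)
    p_value = (1.0 + int((perm_values >= observed).sum())) / (n_perm + 1.0)
    return MatrixCorrelationResult(observed, p_value, n_perm, include_diagonal,
                                   seed_out, perm_values)


# ---------------------------------------------------------------------------
# Integration metrics
# ---------------------------------------------------------------------------

def integration_metrics(S_module: np.ndarray, p_vars: int | None = None) -> dict[str, float]:
    """Eigenvalue-variance integration metrics of a module covariance block.

    Returns a dict with keys ``tvc`` (trace), ``ev_var`` (population variance
    of the eigenvalues, divisor p), ``evstv`` (= ev_var / tvc^2) and
    ``evstvnv`` (relative eigenvalue variance, in [0, 1]).
    """
    S_module = np.asarray(S_module, float)
    if p_vars is None:
        p_vars = S_module.shape[0]
    evals = np.linalg.eigvalsh(S_module)
    tvc = float(evals.sum())
    if tvc <= 0:
        raise ValueError("degenerate module: total variance is zero")
    lam_bar = tvc / p_vars
    ev_var = float(((evals - lam_bar) ** 2).sum()) / p_vars
    evstv = ev_var / tvc ** 2
    evstvnv = ev_var / (lam_bar ** 2 * (p_vars - 1))
    return {"tvc": tvc, "ev_var": ev_var, "evstv": evstv, "evstvnv": evstvnv}


def integration_table(
    covset: CovarianceMatrixSet,
    partitions: list[ModulePartition],
    d: int,
    components: tuple[str, ...] = ("asymmetric", "symmetric"),
    include_total: bool = True,
) -> pd.DataFrame:
    """Per-(hypothesis, module, component) integration summary.

    Module covariances are extracted as sub-blocks of the full-shape
    covariance (no per-module re-superimposition).  ``fa_magnitude`` is the
    trace of the module's FA covariance sub-block.  With ``include_total``
    a whole-configuration row (module ``total_face``) is prepended.
    """
    comp_matrix = {"symmetric": covset.individual, "asymmetric": covset.fa}
    rows = []

    def add_row(hypothesis: str, module: str, landmarks) -> None:
        for comp in components:
            sub = landmark_subblock(comp_matrix[comp], landmarks, d)
            metrics = integration_metrics(sub)
            fa_sub = landmark_subblock(covset.fa, landmarks, d)
            rows.append({"hypothesis": hypothesis, "module": module,
                         "component": comp, **metrics,
                         "fa_magnitude": float(np.trace(fa_sub))})

    if include_total:
        k = covset.individual.shape[0] // d
        add_row(partitions[0].name if partitions else "all", "total_face",
                np.arange(k))
    for part in partitions:
        for label in part.modules:
            add_row(part.name, label, part.members(label))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS fit y = a + b x with ANOVA summary and a mean-response band."""

    slope: float
    intercept: float
    r2: float
    rmse: float
    df_model: int
    df_error: int
    ss_model: float
    ss_error: float
    ss_total: float
    f: float
    p_value: float
    correlation: float
    alpha_band: float
    x: np.ndarray
    y: np.ndarray
    lower_band: np.ndarray   # pointwise lower confidence limit at the x's
    upper_band: np.ndarray

    @property
    def ms_model(self) -> float:
        return self.ss_model / self.df_model

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)

    def below_band(self) -> np.ndarray:
        """Boolean flags: observed y below the lower confidence band."""
        return self.y < self.lower_band


def regress(x, y, alpha_band: float = 0.01) -> RegressionResult:
    """Ordinary least squares of y on x with an F-test and confidence band.

    The band is the pointwise confidence interval for the mean response at
    the observed x values, at significance level *alpha_band* (two-sided).
    Requires >= 3 points and non-constant x.
    """
    import statsmodels.api as sm

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    fitted = model.fittedvalues
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_error = float(model.ssr)
    ss_model = float(model.ess)
    df_model, df_error = 1, n - 2
    ms_error = ss_error / df_error
    f = (ss_model / df_model) / ms_error if ms_error > 0 else float("inf")
    p = float(stats.f.sf(f, df_model, df_error))
    pred = model.get_prediction(sm.add_constant(x))
    band = pred.conf_int(alpha=alpha_band)
    r = float(np.sign(slope) * np.sqrt(model.rsquared)) if ss_total > 0 else 0.0
    return RegressionResult(
        slope=float(slope), intercept=float(intercept),
        r2=float(model.rsquared), rmse=float(np.sqrt(ms_error)),
        df_model=df_model, df_error=df_error,
        ss_model=ss_model, ss_error=ss_error, ss_total=ss_total,
        f=float(f), p_value=p, correlation=r, alpha_band=alpha_band,
        x=x, y=y, lower_band=band[:, 0], upper_band=band[:, 1],
    )


def integration_regressions(
    table: pd.DataFrame,
    component: str,
    alpha_band: float = 0.01,
) -> tuple[RegressionResult, RegressionResult, pd.DataFrame]:
    """The two module-level regressions for one shape component.

    Using one point per module row of *table* (an :func:`integration_table`
    output filtered here by component): (1) integration on total variance,
    ``evstv ~ tvc``; (2) FA magnitude on integration, ``fa_magnitude ~
    evstv``.  Returns both fits plus a per-module frame flagging points below
    the lower confidence band of the first regression — modules with more
    variation than expected for their degree of internal integration.
    """
    sub = table[table["component"] == component]
    if sub.empty:
        raise ValueError(f"no rows for component {component!r}")
    sub = sub.drop_duplicates(subset=["module"])
    reg_int = regress(sub["tvc"].to_numpy(), sub["evstv"].to_numpy(), alpha_band)
    reg_fa = regress(sub["evstv"].to_numpy(), sub["fa_magnitude"].to_numpy(),
                     alpha_band)
    flags = pd.DataFrame({
        "module": sub["module"].to_numpy(),
        "component": component,
        "below_band": reg_int.below_band(),
    })
    return reg_int, reg_fa, flags
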