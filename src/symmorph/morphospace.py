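"""PCA morphospaces of the symmetric and asymmetric shape components.

Principal components are the eigenvectors of the covariance matrix of the
flattened component rows.  Group structure is summarized by per-group score
centroids and coverage ellipses: the 2-D score covariance scaled by the
chi-square quantile at the requested coverage, so a 90% ellipse is expected
to contain 90% of a bivariate-normal score cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PCAResult", "GroupEllipse", "pca", "group_summary", "plot_scores"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray       # descending, length p
    loadings: np.ndarray          # (p, p), columns are axes
    scores: np.ndarray            # (n, p)
    proportion: np.ndarray        # variance proportions per axis
    mean: np.ndarray              # (p,) input mean


def pca(component_rows: np.ndarray) -> PCAResult:
    """Eigendecomposition of the covariance of centered rows.

    Axes are ordered by descending eigenvalue; the sign of each loading
    vector is fixed so its largest-magnitude entry is positive.
    """
    rows = np.asarray(component_rows, float)
    if rows.ndim != 2:
        raise ValueError(f"expected (n, p) rows, got shape {rows.shape}")
    n = rows.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 specimens, got {n}")
    mean = rows.mean(axis=0)
    centered = rows - mean
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        peak = np.argmax(np.abs(evecs[:, j]))
        if evecs[peak, j] < 0:
            evecs[:, j] *= -1.0
    scores = centered @ evecs
    total = evals.sum()
    proportion = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(evals, evecs, scores, proportion, mean)


@dataclass
class GroupEllipse:
    group: str
    n: int
    centroid: np.ndarray          # (2,) mean score on the two axes
    cov: np.ndarray               # (2, 2) score covariance
    semi_axes: np.ndarray         # (2,) ellipse semi-axis lengths
    angle: float                  # radians, major axis vs first score axis
    coverage: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether 2-D points fall inside the coverage ellipse."""
        dev = np.asarray(points, float) - self.centroid
        m = np.einsum("ni,ij,nj->n", dev, np.linalg.inv(self.cov), dev)
        return m <= stats.chi2.ppf(self.coverage, df=2)


def group_summary(
    scores: np.ndarray,
    labels,
    axes: tuple[int, int] = (0, 1),
    coverage: float = 0.90,
) -> dict[str, GroupEllipse]:
    """Per-group centroids and coverage ellipses in a 2-D score plane.

    Groups with fewer than 3 members are skipped with a warning.  Ellipse
    semi-axes are ``sqrt(eigenvalue * chi2.ppf(coverage, 2))`` of the group
    score covariance.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, object)
    plane = scores[:, list(axes)]
    out: dict[str, GroupEllipse] = {}
    for group in dict.fromkeys(labels):
        pts = plane[labels == group]
        if pts.shape[0] < 3:
            warnings.warn(f"group {group!r} has <3 specimens; skipped")
            continue
        centroid = pts.mean(axis=0)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        scale = stats.chi2.ppf(coverage, df=2)
        out[str(group)] = GroupEllipse(
            group=str(group), n=pts.shape[0], centroid=centroid, cov=cov,
            semi_axes=np.sqrt(evals * scale),
            angle=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
            coverage=coverage,
        )
    return out


def plot_scores(result: PCAResult, labels=None, axes: tuple[int, int] = (0, 1),
                coverage: float = 0.90, path=None):
    """Static scatter plot of two score axes with optional group ellipses."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(result.scores[:, i], result.scores[:, j], s=8, alpha=0.6)
    else:
        labels = np.asarray(labels, object)
        ellipses = group_summary(result.scores, labels, axes, coverage)
        for group in dict.fromkeys(labels):
            mask = labels == group
            pts = ax.scatter(result.scores[mask, i], result.scores[mask, j],
                             s=8, alpha=0.6, label=str(group))
            ell = ellipses.get(str(group))
            if ell is not None:
                theta = np.linspace(0, 2 * np.pi, 200)
                circ = np.stack([ell.semi_axes[0] * np.cos(theta),
                                 ell.semi_axes[1] * np.sin(theta)])
                rot = np.array([[np.cos(ell.angle), -np.sin(ell.angle)],
                                [np.sin(ell.angle), np.cos(ell.angle)]])
                arc = rot @ circ + ell.centroid[:, None]
                ax.plot(arc[0], arc[1], color=pts.get_facecolor()[0], lw=1.2)
        ax.legend(fontsize=8)
    ax.set_xlabel(f"PC{i + 1} ({100 * result.proportion[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * result.proportion[j]:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def scores_frame(result: PCAResult, specimen_ids, n_axes: int = 10) -> pd.DataFrame:
    n_axes = min(n_axes, result.scores.shape[1])
    data = {"specimen_id": list(specimen_ids)}
    for j in range(n_axes):
        data[f"PC{j + 1}"] = result.scores[:, j]
    return pd.DataFrame(data)
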