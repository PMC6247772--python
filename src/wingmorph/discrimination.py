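"""Discriminant analysis of shape variables.

Canonical variate analysis (CVA, the multi-group discriminant analysis)
maximizes between-group relative to pooled within-group variation.  Because
shape-variable spaces (partial-warp scores, normalized Fourier
coefficients) can have more dimensions than specimens, variables are first
reduced by principal components to the smallest number of axes explaining a
requested variance fraction, hard-capped at n - g so the pooled
within-group covariance is invertible.

The squared Mahalanobis distance between groups i and j is
D^2 = (mu_i - mu_j)^T S_pooled^-1 (mu_i - mu_j) on the retained space.
Specimens are classified to the group whose mean is nearest in Mahalanobis
distance (equal priors — distance only); validated (leave-one-out)
reclassification re-estimates the whole model, including the PC reduction,
without the held-out specimen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "DiscriminantModel",
    "ReclassificationReport",
    "DiscriminationError",
    "fit_da",
    "factor_map",
    "loo_reclassify",
    "mahalanobis_matrix",
]


class DiscriminationError(ValueError):
    """Raised for undersized groups or singular covariance structure."""


@dataclass
class DiscriminantModel:
    group_labels: list               # ordered species list, length g
    canonical_axes: np.ndarray       # (p', n_axes) loadings on retained PCs
    factor_scores: np.ndarray        # (n, n_axes)
    pooled_cov: np.ndarray           # (p', p') within-group covariance
    mahalanobis: np.ndarray          # (g, g) distances D
    retained_dims: int               # p'
    pc_loadings: np.ndarray          # (p, p') reduction applied first
    pc_center: np.ndarray            # (p,)
    group_means: np.ndarray          # (g, p') on the retained space
    labels: np.ndarray               # (n,) specimen labels

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass
class ReclassificationReport:
    group_labels: list
    confusion: np.ndarray            # (g, g) true x assigned counts
    per_species: dict                # label -> (correct, total, percent)
    overall_percent: float

    def to_frame(self):
        import pandas as pd

        rows = {
            lab: f"{round(100 * c / t)}% ({c}/{t})"
            for lab, (c, t, _) in self.per_species.items()
        }
        return pd.DataFrame(
            {"reclassification": [rows[g] for g in self.group_labels]},
            index=self.group_labels,
        )


def _validate_groups(x: np.ndarray, labels: np.ndarray, min_size: int) -> list:
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise DiscriminationError("discrimination needs at least 2 groups")
    for g in groups:
        n_g = int(np.sum(labels == g))
        if n_g < min_size:
            raise DiscriminationError(
                f"group {g!r} has {n_g} specimens (minimum {min_size})"
            )
    return groups


def _pc_reduce(
    x: np.ndarray, var_fraction: float, max_dims: int
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component reduction: center, project onto the fewest axes
    explaining >= var_fraction of total variance, capped at max_dims.
    Returns (center, loadings)."""
    center = x.mean(axis=0)
    xc = x - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-20 * max(1.0, float(np.sum(center**2))):
        raise DiscriminationError("shape variables have zero total variance")
    frac = np.cumsum(var) / total
    n_keep = int(np.searchsorted(frac, var_fraction - 1e-12) + 1)
    n_keep = min(n_keep, max_dims)
    # never keep axes with (numerically) zero variance
    nonzero = int(np.sum(var > total * 1e-12))
    n_keep = max(1, min(n_keep, nonzero))
    return center, vt[:n_keep].T


def _pooled_cov(
    z: np.ndarray, labels: np.ndarray, groups: list
) -> tuple[np.ndarray, np.ndarray]:
    """Group means and pooled within-group covariance on z."""
    n, p = z.shape
    g = len(groups)
    means = np.empty((g, p))
    ss = np.zeros((p, p))
    for i, lab in enumerate(groups):
        zi = z[labels == lab]
        means[i] = zi.mean(axis=0)
        d = zi - means[i]
        ss += d.T @ d
    dof = n - g
    if dof <= 0:
        raise DiscriminationError("no within-group degrees of freedom")
    pooled = ss / dof
    total_scale = float(np.var(z, axis=0).sum())
    if np.trace(pooled) <= 1e-15 * max(total_scale, 1e-300):
        raise DiscriminationError(
            "degenerate within-group covariance: no within-group variance"
        )
    return means, pooled


def _mahalanobis_from(means: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    g = means.shape[0]
    try:
        chol = cho_factor(pooled)
    except np.linalg.LinAlgError as exc:
        raise DiscriminationError(
            "pooled within-group covariance is singular after reduction"
        ) from exc
    d = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            diff = means[i] - means[j]
            d2 = float(diff @ cho_solve(chol, diff))
            d[i, j] = d[j, i] = np.sqrt(max(d2, 0.0))
    return d


def mahalanobis_matrix(
    shape_vars: np.ndarray,
    labels,
    var_fraction: float = 0.95,
) -> tuple[list, np.ndarray]:
    """Pairwise Mahalanobis distance matrix after PC reduction.

    Lighter entry point than :func:`fit_da` for permutation tests and
    bootstrap resampling; same reduction and distance rules.
    """
    x = np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    groups = _validate_groups(x, labels, min_size=2)
    max_dims = x.shape[0] - len(groups)
    center, loadings = _pc_reduce(x, var_fraction, max_dims)
    z = (x - center) @ loadings
    means, pooled = _pooled_cov(z, labels, groups)
    return groups, _mahalanobis_from(means, pooled)


def fit_da(
    shape_vars: np.ndarray,
    labels,
    var_fraction: float = 0.95,
) -> DiscriminantModel:
    """Fit the canonical variate / discriminant model.

    Canonical axes solve the generalized eigenproblem
    S_between v = lambda S_pooled v on the PC-reduced space; at most g - 1
    axes carry between-group signal.  Factor scores are the centered
    reduced variables projected on those axes.
    """
    x = np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    if x.ndim != 2:
        raise DiscriminationError("shape_vars must be 2-D (specimens x variables)")
    groups = _validate_groups(x, labels, min_size=2)
    g = len(groups)
    n = x.shape[0]
    max_dims = n - g
    if max_dims < 1:
        raise DiscriminationError("more groups than spare specimens")
    center, loadings = _pc_reduce(x, var_fraction, max_dims)
    z = (x - center) @ loadings
    means, pooled = _pooled_cov(z, labels, groups)
    d = _mahalanobis_from(means, pooled)

    # between-group covariance, weighted by group sizes
    grand = z.mean(axis=0)
    sb = np.zeros((z.shape[1],) * 2)
    for i, lab in enumerate(groups):
        n_i = int(np.sum(labels == lab))
        diff = means[i] - grand
        sb += n_i * np.outer(diff, diff)
    sb /= n
    n_axes = min(g - 1, z.shape[1])
    evals, evecs = eigh(sb, pooled)
    order = np.argsort(evals)[::-1][:n_axes]
    axes = evecs[:, order]
    for j in range(axes.shape[1]):  # deterministic axis signs
        m = np.argmax(np.abs(axes[:, j]))
        if axes[m, j] < 0:
            axes[:, j] = -axes[:, j]
    scores = (z - grand) @ axes

    return DiscriminantModel(
        group_labels=groups,
        canonical_axes=axes,
        factor_scores=scores,
        pooled_cov=pooled,
        mahalanobis=d,
        retained_dims=z.shape[1],
        pc_loadings=loadings,
        pc_center=center,
        group_means=means,
        labels=labels,
    )


def factor_map(model: DiscriminantModel):
    """Per-specimen coordinates on the first two canonical axes plus the
    convex hull of each group (vertex coordinate arrays).

    With two groups there is a single canonical axis; the second coordinate
    is identically zero.
    """
    scores = model.factor_scores
    if scores.shape[1] >= 2:
        xy = scores[:, :2].copy()
    else:
        xy = np.column_stack([scores[:, 0], np.zeros(scores.shape[0])])
    hulls = {}
    for lab in model.group_labels:
        pts = xy[model.labels == lab]
        if pts.shape[0] >= 3:
            try:
                hull = ConvexHull(pts)
                hulls[lab] = pts[hull.vertices]
            except QhullError:  # collinear group
                hulls[lab] = pts
        else:
            hulls[lab] = pts
    return xy, hulls


def loo_reclassify(
    shape_vars: np.ndarray,
    labels,
    var_fraction: float = 0.95,
) -> ReclassificationReport:
    """Validated (leave-one-out) reclassification.

    For every specimen the PC reduction, group means and pooled covariance
    are re-estimated without it; the specimen is then assigned to the group
    with the smallest Mahalanobis distance.  Distance ties are broken
    toward the first group in label order.
    """
    x = np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    groups = _validate_groups(x, labels, min_size=3)
    g = len(groups)
    index = {lab: i for i, lab in enumerate(groups)}
    confusion = np.zeros((g, g), dtype=int)
    n = x.shape[0]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_train, lab_train = x[mask], labels[mask]
        max_dims = x_train.shape[0] - g
        center, loadings = _pc_reduce(x_train, var_fraction, max_dims)
        z_train = (x_train - center) @ loadings
        means, pooled = _pooled_cov(z_train, lab_train, groups)
        chol = cho_factor(pooled)
        z_i = (x[i] - center) @ loadings
        d2 = np.array(
            [float((z_i - m) @ cho_solve(chol, z_i - m)) for m in means]
        )
        assigned = int(np.argmin(d2))  # argmin takes the first on ties
        confusion[index[labels[i]], assigned] += 1
    per_species = {}
    for lab in groups:
        i = index[lab]
        total = int(confusion[i].sum())
        correct = int(confusion[i, i])
        per_species[lab] = (correct, total, 100.0 * correct / total)
    overall = 100.0 * float(np.trace(confusion)) / n
    return ReclassificationReport(
        group_labels=groups,
        confusion=confusion,
        per_species=per_species,
        overall_percent=overall,
    )
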