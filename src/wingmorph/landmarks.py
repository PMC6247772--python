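"""Landmark-based size and shape variables.

Size is the centroid size (CS): the square root of the summed squared
distances of the landmarks from their centroid, converted to mm by the
specimen's scale factor.  Shape is extracted by Generalised Procrustes
Analysis (GPA): every configuration is centered, scaled to unit centroid
size and rotated to an iteratively re-estimated consensus (partial
Procrustes — the scale stays fixed at 1 during the rotation step, the
standard convention when CS is analyzed as a separate size variable).
Reflections are never allowed: wings are chiral and only one side is
digitized.

Shape variables are the partial-warp scores (PW): projections of the
tangent-space residuals onto the eigenvectors of the consensus
bending-energy matrix (the non-affine basis) plus the two affine (uniform)
components, an orthonormal basis of the 2K-4 dimensional shape tangent
space.  Relative warps (RW) are the principal components of the PW scores
(no bending-energy re-weighting, i.e. alpha = 0).

Residual convention: a specimen's residual is the orthogonal projection of
(aligned - consensus) onto the tangent space at the consensus (the
component along the unit-norm consensus vector removed).  This removes a
second-order radial term so the orthonormal PW basis carries the residual
variance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space, svd

from .io import LandmarkConfiguration, MorphoDataset

__all__ = [
    "ProcrustesFit",
    "GPAError",
    "centroid_size",
    "gpa",
    "partial_warps",
    "relative_warps",
    "align_pair",
    "procrustes_distance_pair",
]


class GPAError(ValueError):
    """Raised for degenerate configurations or non-convergent fits."""


def centroid_size(config: LandmarkConfiguration) -> float:
    """Centroid size in mm.

    CS = scale * sqrt(sum_i ||p_i - centroid||^2).
    """
    coords = config.coords
    if coords.shape[0] < 2:
        raise GPAError(f"{config.specimen_id}: need at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise GPAError(
            f"{config.specimen_id}: all landmarks coincide (centroid size 0)"
        )
    return config.scale * cs


def _preshape(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    c = coords - coords.mean(axis=0)
    norm = np.sqrt(np.sum(c**2))
    if norm == 0:
        raise GPAError("degenerate configuration: zero centroid size")
    return c / norm


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (2x2, det=+1) minimizing ||source @ R - target||.

    Closed form via SVD of the cross-covariance; reflections disallowed.
    """
    m = source.T @ target
    u, _, vt = svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, d])
    return u @ corr @ vt


def align_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-shape ordinary Procrustes: preshapes of a and b with b rotated
    onto a (closed-form optimal rotation, no reflection)."""
    za, zb = _preshape(np.asarray(a, float)), _preshape(np.asarray(b, float))
    return za, zb @ _optimal_rotation(zb, za)


def procrustes_distance_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two raw configurations:
    ||preshape(a) - R-aligned preshape(b)||."""
    za, zb = align_pair(a, b)
    return float(np.linalg.norm(za - zb))


@dataclass
class ProcrustesFit:
    """Result of a Generalised Procrustes Analysis.

    ``aligned`` holds the superimposed unit-CS configurations,
    ``residuals`` their tangent-space deviations from ``mean_shape``,
    ``pw_scores``/``rw_scores`` the derived shape variables.
    """

    specimen_ids: list
    species: list
    mean_shape: np.ndarray          # (K, 2), centered, unit CS
    aligned: np.ndarray             # (n, K, 2)
    centroid_sizes: np.ndarray      # (n,), mm
    residuals: np.ndarray           # (n, K, 2), tangent-space
    iterations: int
    converged: bool
    pw_scores: np.ndarray | None = None      # (n, 2K-4)
    rw_scores: np.ndarray | None = None      # (n, 2K-4)
    rw_explained: np.ndarray | None = None   # fractions, sum 1

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]

    def procrustes_distance(self, i: int, j: int) -> float:
        """Partial Procrustes distance between specimens i and j, computed
        by optimally re-rotating one aligned copy onto the other."""
        return procrustes_distance_pair(self.aligned[i], self.aligned[j])


def _principal_axis_rotation(shape: np.ndarray) -> np.ndarray:
    """Rotation sending the shape's major principal axis to +x.

    Orientation fixed by giving the landmark furthest from the centroid a
    positive x coordinate (the only remaining freedom is a 180-degree
    proper rotation; reflections are never applied — wings are chiral).
    """
    cov = shape.T @ shape
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    r = evecs[:, order]
    if np.linalg.det(r) < 0:
        r[:, 1] = -r[:, 1]
    rotated = shape @ r
    far = int(np.argmax(np.sum(rotated**2, axis=1)))
    if rotated[far, 0] < 0:
        r = r @ np.diag([-1.0, -1.0])
    return r


def gpa(
    dataset: MorphoDataset,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Generalised Procrustes Analysis (partial Procrustes superimposition).

    Each configuration is centered and scaled to unit centroid size, then
    rotated to the current consensus; the consensus is the re-normalized
    mean of the aligned configurations, iterated until its Frobenius change
    drops below ``tol``.  The converged consensus is aligned to its
    principal axes so the orientation of shape space is reproducible.

    Raises
    ------
    GPAError
        If fewer than 2 specimens, landmark counts differ, or the fit does
        not converge in ``max_iter`` iterations.
    """
    records = list(dataset.records)
    if len(records) < 2:
        raise GPAError("GPA needs at least 2 specimens")
    ks = {r.coords.shape[0] for r in records}
    if len(ks) != 1:
        raise GPAError(f"landmark-count mismatch across specimens: {sorted(ks)}")

    sizes = np.array([centroid_size(r) for r in records])
    pre = np.stack([_preshape(r.coords) for r in records])  # (n, K, 2)
    n = pre.shape[0]

    mean = pre[0].copy()
    mean = _preshape(mean)
    aligned = pre.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = pre[i] @ _optimal_rotation(pre[i], mean)
        new_mean = _preshape(aligned.mean(axis=0))
        # resolve the arbitrary rotation of the new consensus toward the old
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        change = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        raise GPAError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e})"
        )

    r_pa = _principal_axis_rotation(mean)
    mean = mean @ r_pa
    for i in range(n):
        aligned[i] = pre[i] @ _optimal_rotation(pre[i], mean)

    # tangent-space residuals: remove the component along the unit consensus
    flat_mean = mean.ravel()
    flat = aligned.reshape(n, -1) - flat_mean
    flat = flat - np.outer(flat @ flat_mean, flat_mean)
    residuals = flat.reshape(aligned.shape)

    return ProcrustesFit(
        specimen_ids=[r.specimen_id for r in records],
        species=[r.species for r in records],
        mean_shape=mean,
        aligned=aligned,
        centroid_sizes=sizes,
        residuals=residuals,
        iterations=iterations,
        converged=converged,
    )


def _bending_energy_eigvecs(mean: np.ndarray) -> np.ndarray:
    """Eigenvectors (columns) of the consensus bending-energy matrix with
    non-zero eigenvalue, ordered by decreasing bending energy.

    The bending-energy matrix is the upper-left K x K block of the inverse
    of the thin-plate-spline system [[S, Q], [Q^T, 0]] with kernel
    sigma(r) = r^2 log r^2 and Q = [1 | x | y].  Its null space is the
    affine (uniform) subspace.
    """
    k = mean.shape[0]
    d2 = np.sum((mean[:, None, :] - mean[None, :, :]) ** 2, axis=2)
    if np.any((d2 == 0) & ~np.eye(k, dtype=bool)):
        raise GPAError("consensus has coincident landmarks: singular TPS kernel")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    q = np.column_stack([np.ones(k), mean])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = s
    l[:k, k:] = q
    l[k:, :k] = q.T
    be = np.linalg.inv(l)[:k, :k]
    be = 0.5 * (be + be.T)
    evals, evecs = np.linalg.eigh(be)
    # three (numerically) zero eigenvalues span the affine subspace
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    nonzero = evecs[:, : k - 3]
    # deterministic sign: largest-|.| entry positive
    for j in range(nonzero.shape[1]):
        m = np.argmax(np.abs(nonzero[:, j]))
        if nonzero[m, j] < 0:
            nonzero[:, j] = -nonzero[:, j]
    return nonzero


def pw_basis(mean: np.ndarray) -> np.ndarray:
    """Orthonormal partial-warp basis: (2K, 2K-4) matrix whose columns are
    the non-affine partial-warp axes (x- and y-copies of the bending-energy
    eigenvectors) followed by the two uniform components.

    The uniform components are the orthogonal complement of the non-affine
    subspace within the shape tangent space (translations, the consensus
    direction and its 90-degree rotation removed).
    """
    k = mean.shape[0]
    nz = _bending_energy_eigvecs(mean)  # (K, K-3)
    cols = []
    for j in range(nz.shape[1]):
        vx = np.zeros((k, 2))
        vx[:, 0] = nz[:, j]
        vy = np.zeros((k, 2))
        vy[:, 1] = nz[:, j]
        cols.append(vx.ravel())
        cols.append(vy.ravel())
    nonaffine = np.column_stack(cols)  # (2K, 2K-6)

    flat_mean = mean.ravel()
    rot90 = np.column_stack([-mean[:, 1], mean[:, 0]]).ravel()
    tx = np.tile([1.0, 0.0], k) / np.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / np.sqrt(k)
    killed = np.column_stack(
        [nonaffine, flat_mean, rot90 / np.linalg.norm(rot90), tx, ty]
    )
    uniform = null_space(killed.T)
    if uniform.shape[1] != 2:
        raise GPAError(
            f"uniform subspace has dimension {uniform.shape[1]}, expected 2"
        )
    # orient the 2-D uniform subspace deterministically by projecting the
    # symmetric-shear (y, x) and anisotropic-dilation (x, -y) fields of the
    # consensus onto it; the two simple shears are congruent modulo rotation
    # so they span only one direction, while these two generate the whole
    # affine-modulo-similarity plane (null_space alone returns an arbitrary
    # rotation of it)
    shear = np.column_stack([mean[:, 1], mean[:, 0]]).ravel()
    dilation = np.column_stack([mean[:, 0], -mean[:, 1]]).ravel()
    proj = uniform @ (uniform.T @ np.column_stack([shear, dilation]))
    q, r = np.linalg.qr(proj)
    if np.linalg.matrix_rank(r, tol=1e-10) == 2:
        uniform = q * np.sign(np.diag(r))
    else:  # degenerate shears: fall back to sign-fixed null-space basis
        for j in range(2):
            m = np.argmax(np.abs(uniform[:, j]))
            if uniform[m, j] < 0:
                uniform[:, j] = -uniform[:, j]
    return np.column_stack([nonaffine, uniform])


def partial_warps(fit: ProcrustesFit) -> np.ndarray:
    """Partial-warp scores, including the two uniform components.

    Rows are specimens, columns the 2K-4 partial-warp axes.  Because the
    basis is an orthonormal rotation of the tangent space, the total score
    variance equals the total residual variance.  The fit's ``pw_scores``
    field is populated in place and the scores returned.
    """
    if not fit.converged:
        raise GPAError("partial warps require a converged GPA fit")
    basis = pw_basis(fit.mean_shape)
    flat = fit.residuals.reshape(fit.n_specimens, -1)
    scores = flat @ basis
    fit.pw_scores = scores
    return scores


def relative_warps(fit: ProcrustesFit) -> tuple[np.ndarray, np.ndarray]:
    """Relative warps: principal components of the partial-warp scores
    (covariance PCA, alpha = 0, no re-weighting).

    Returns ``(scores, explained)`` where ``explained`` are the
    explained-variance fractions (non-increasing, summing to 1).  Axis
    signs are fixed by making the largest-|loading| entry positive.
    """
    if fit.pw_scores is None:
        partial_warps(fit)
    pw = fit.pw_scores
    if pw.shape[0] < 2:
        raise GPAError("relative warps need at least 2 specimens")
    centered = pw - pw.mean(axis=0)
    u, s, vt = svd(centered, full_matrices=False)
    for j in range(vt.shape[0]):
        m = np.argmax(np.abs(vt[j]))
        if vt[j, m] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = centered @ vt.T
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    fit.rw_scores = scores
    fit.rw_explained = explained
    return scores, explained
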