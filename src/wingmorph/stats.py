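"""Permutation inference, repeatability and allometry.

Pairwise species differences in size (centroid size or perimeter) and
shape (Mahalanobis distance) are tested by label permutation within each
species pair, with Bonferroni correction over the g(g-1)/2 pairs.  The
p-value convention is the exact-test form (1 + #{null >= observed}) /
(1 + n_perm), so p is never 0 and the observed statistic is a member of
its own reference set.

Digitization precision is summarized by the repeatability index R, the
one-way-ANOVA intraclass correlation
R = (MS_among - MS_within) / (MS_among + (k - 1) MS_within),
truncated to 0 when negative.

Allometry is the dependence of shape on size: each discriminant factor is
linearly regressed on size and the per-factor R^2 values are pooled,
weighted by factor variance, into a single percent-of-variance figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .discrimination import DiscriminationError, _pc_reduce, _pooled_cov

__all__ = [
    "PermutationResult",
    "RepeatabilityResult",
    "AllometryResult",
    "perm_test_size",
    "perm_test_shape",
    "bonferroni",
    "repeatability",
    "allometry",
    "quantile_summary",
    "significance_letters",
]

DEFAULT_N_PERM = 1000
DEFAULT_SEED = 20180611


@dataclass
class PermutationResult:
    observed: float
    null_stats: np.ndarray
    p_raw: float
    n_perm: int
    p_adj: float | None = None

    def adjust(self, m: int) -> "PermutationResult":
        self.p_adj = min(1.0, m * self.p_raw)
        return self


@dataclass
class RepeatabilityResult:
    r: float
    ms_among: float
    ms_within: float
    n_specimens: int
    k_replicates: int


@dataclass
class AllometryResult:
    r2_percent: float
    slopes: np.ndarray        # per-factor regression slope on size
    correlations: np.ndarray  # per-factor Pearson r with size


def _p_value(observed: float, null_stats: np.ndarray) -> float:
    return (1.0 + float(np.sum(null_stats >= observed))) / (1.0 + null_stats.size)


def perm_test_size(
    values,
    labels,
    group_a: str,
    group_b: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
) -> PermutationResult:
    """Permutation test for a difference in mean size between two species.

    Statistic: |mean(a) - mean(b)|.  Labels are permuted within the pooled
    pair only.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    group_a, group_b = sorted((group_a, group_b))  # symmetric in roles
    a = values[labels == group_a]
    b = values[labels == group_b]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    observed = abs(float(a.mean() - b.mean()))
    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = abs(float(perm[:n_a].mean() - perm[n_a:].mean()))
    return PermutationResult(observed, null, _p_value(observed, null), n_perm)


def _pair_mahalanobis_machinery(x: np.ndarray, var_fraction: float):
    """PC-reduce a pooled two-group sample once (the reduction is
    label-free, hence identical under every label permutation)."""
    max_dims = x.shape[0] - 2
    if max_dims < 1:
        raise DiscriminationError("pair too small for a Mahalanobis distance")
    center, loadings = _pc_reduce(x, var_fraction, max_dims)
    return (x - center) @ loadings


def _pair_d(z: np.ndarray, is_a: np.ndarray) -> float:
    za, zb = z[is_a], z[~is_a]
    n = z.shape[0]
    ma, mb = za.mean(axis=0), zb.mean(axis=0)
    da, db = za - ma, zb - mb
    pooled = (da.T @ da + db.T @ db) / (n - 2)
    diff = ma - mb
    try:
        chol = cho_factor(pooled)
    except np.linalg.LinAlgError as exc:
        raise DiscriminationError(
            "singular pooled covariance in pairwise shape test"
        ) from exc
    return float(np.sqrt(max(diff @ cho_solve(chol, diff), 0.0)))


def perm_test_shape(
    shape_vars,
    labels,
    group_a: str,
    group_b: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
    var_fraction: float = 0.95,
) -> PermutationResult:
    """Permutation test for a shape difference between two species.

    Statistic: the pairwise Mahalanobis distance D, recomputed under each
    within-pair label permutation (group sizes preserved).
    """
    shape_vars = np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    group_a, group_b = sorted((group_a, group_b))  # symmetric in roles
    sel = (labels == group_a) | (labels == group_b)
    x = shape_vars[sel]
    lab = labels[sel]
    n_a = int(np.sum(lab == group_a))
    n_b = int(np.sum(lab == group_b))
    if n_a < 2 or n_b < 2:
        raise DiscriminationError(
            f"both groups need >= 2 specimens ({group_a!r}: {n_a}, {group_b!r}: {n_b})"
        )
    z = _pair_mahalanobis_machinery(x, var_fraction)
    is_a = lab == group_a
    observed = _pair_d(z, is_a)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = z.shape[0]
    for i in range(n_perm):
        perm_a = np.zeros(n, dtype=bool)
        perm_a[rng.choice(n, size=n_a, replace=False)] = True
        null[i] = _pair_d(z, perm_a)
    return PermutationResult(observed, null, _p_value(observed, null), n_perm)


def bonferroni(p_values, m: int):
    """Bonferroni adjustment: multiply each p by m, cap at 1."""
    p = np.asarray(p_values, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def repeatability(measurements) -> RepeatabilityResult:
    """Repeatability index R from a one-way ANOVA over replicate
    digitizations.

    ``measurements`` is an (n_specimens, k_replicates) array of the same
    scalar measured k times per specimen.  R estimates the intraclass
    correlation sigma^2_among / (sigma^2_among + sigma^2_within); negative
    point estimates are truncated to 0.
    """
    x = np.asarray(measurements, float)
    if x.ndim != 2:
        raise ValueError("measurements must be n_specimens x k_replicates")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 specimens")
    if k < 2:
        raise ValueError("need at least 2 replicates per specimen")
    if np.ptp(x) == 0:
        raise ValueError("all measurements identical: repeatability undefined")
    spec_means = x.mean(axis=1)
    grand = x.mean()
    ms_among = k * float(np.sum((spec_means - grand) ** 2)) / (n - 1)
    ms_within = float(np.sum((x - spec_means[:, None]) ** 2)) / (n * (k - 1))
    r = (ms_among - ms_within) / (ms_among + (k - 1) * ms_within)
    return RepeatabilityResult(max(r, 0.0), ms_among, ms_within, n, k)


def coordinate_repeatability(first, second) -> np.ndarray:
    """Per-coordinate repeatability across two replicate digitizations.

    ``first`` and ``second`` are (n, K, 2) landmark arrays (or (n, M, 2)
    contours); returns a (K, 2) array of R values, one per coordinate.
    """
    a = np.asarray(first, float)
    b = np.asarray(second, float)
    if a.shape != b.shape:
        raise ValueError("replicate arrays must have identical shape")
    out = np.empty(a.shape[1:])
    for j in range(a.shape[1]):
        for c in range(a.shape[2]):
            out[j, c] = repeatability(np.column_stack([a[:, j, c], b[:, j, c]])).r
    return out


def allometry(factor_scores, sizes) -> AllometryResult:
    """Allometric effect: percent of discriminant-factor variance
    explained by linear regression on size.

    Each factor is regressed on size; per-factor R^2 values are pooled
    weighted by factor variance, so r2_percent is the fraction of total
    factor-score variance lying along size.
    """
    scores = np.asarray(factor_scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    sizes = np.asarray(sizes, float)
    if scores.shape[0] != sizes.shape[0]:
        raise ValueError("factor_scores and sizes must align per specimen")
    s_var = float(np.var(sizes))
    if s_var == 0:
        raise ValueError("sizes are constant: allometry undefined")
    sc = sizes - sizes.mean()
    slopes = np.empty(scores.shape[1])
    corrs = np.empty(scores.shape[1])
    f_vars = scores.var(axis=0)
    explained = 0.0
    for j in range(scores.shape[1]):
        fc = scores[:, j] - scores[:, j].mean()
        cov = float(np.mean(fc * sc))
        slopes[j] = cov / s_var
        corrs[j] = cov / np.sqrt(s_var * f_vars[j]) if f_vars[j] > 0 else 0.0
        explained += corrs[j] ** 2 * f_vars[j]
    total = float(f_vars.sum())
    r2 = 100.0 * explained / total if total > 0 else 0.0
    return AllometryResult(r2, slopes, corrs)


def quantile_summary(values, labels) -> pd.DataFrame:
    """Per-species size summary: P25, median, P75, min, max, mean, SD.

    Quantiles use the linear-interpolation convention.  Rows are species in
    sorted label order.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    rows = []
    species = sorted(set(labels.tolist()))
    for lab in species:
        v = values[labels == lab]
        rows.append(
            {
                "n": v.size,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                "min": v.min(),
                "p25": np.percentile(v, 25),
                "median": np.percentile(v, 50),
                "p75": np.percentile(v, 75),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows, index=species)


def significance_letters(labels: list, p_adj: dict, alpha: float = 0.05) -> dict:
    """Compact-letter display for pairwise tests.

    Groups joined by an edge whenever their pairwise adjusted p >= alpha;
    connected components of that non-significant-pair graph share a letter.
    ``p_adj`` maps frozenset({a, b}) -> adjusted p-value.
    """
    import string

    labels = list(labels)
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair, p in p_adj.items():
        a, b = sorted(pair)
        if p >= alpha:
            parent[find(a)] = find(b)
    roots = []
    letters = {}
    for lab in labels:
        r = find(lab)
        if r not in roots:
            roots.append(r)
        letters[lab] = string.ascii_lowercase[roots.index(r)]
    return letters
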