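"""Outline-based size and shape variables: elliptic Fourier analysis.

Size is the perimeter length of the closed contour in mm.  Shape is the
vector of normalized elliptic Fourier coefficients (NEF): the contour's
x(t) and y(t) are decomposed into harmonic quadruples (a_n, b_n, c_n, d_n)
and standardized for size, rotation and starting point using the
first-harmonic ellipse, leaving 4H - 3 free coefficients.

Parameterization convention
---------------------------
Vertices are treated as equally spaced in the curve parameter t.  Contours
are resampled to equal arc-length spacing before decomposition (the
pipeline does this), at which point t is proportional to arc length.  This
convention — rather than cumulative chord length on the raw polygon — is
what makes an ellipse sampled at uniform phase an exactly one-harmonic
curve; the classic chord-length weighting of Kuhl & Giardina is available
via ``parameterization="chord"`` and coincides with the default on
equally-spaced contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MorphoIOError, OutlineContour, signed_area

__all__ = [
    "EFADecomposition",
    "resample_contour",
    "perimeter_length",
    "efa",
    "normalize_efa",
    "reconstruct",
]

#: higher-harmonic magnitude below which two normalization candidates are
#: considered indistinguishable when breaking the 180-degree phase tie
_TIE_EPS = 1e-9


@dataclass
class EFADecomposition:
    """Elliptic Fourier decomposition of one closed contour."""

    specimen_id: str
    species: str
    harmonics: np.ndarray          # (H, 4): rows (a_n, b_n, c_n, d_n)
    offset: np.ndarray             # (2,): (A0, C0) curve centroid
    perimeter: float               # mm
    n_harmonics: int
    nef: np.ndarray | None = None  # (4H - 3,) after normalize_efa
    normalized_harmonics: np.ndarray | None = None  # (H, 4)

    @property
    def H(self) -> int:
        return self.n_harmonics


def perimeter_length(contour: OutlineContour) -> float:
    """Closed-polyline perimeter in mm (scale x pixel length)."""
    pts = contour.points
    closed = np.vstack([pts, pts[:1]]) if contour.closed else pts
    seg = np.sqrt(np.sum(np.diff(closed, axis=0) ** 2, axis=1))
    return contour.scale * float(seg.sum())


def resample_contour(contour: OutlineContour, n_points: int) -> OutlineContour:
    """Resample a closed contour to ``n_points`` equally spaced by arc
    length, preserving the starting point and orientation."""
    if not contour.closed:
        raise MorphoIOError(
            f"{contour.specimen_id}: resampling requires a closed contour"
        )
    if n_points < 8:
        raise MorphoIOError("n_points must be at least 8")
    pts = contour.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.sqrt(np.sum(np.diff(closed, axis=0) ** 2, axis=1))
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    targets = total * np.arange(n_points) / n_points
    new_x = np.interp(targets, t, closed[:, 0])
    new_y = np.interp(targets, t, closed[:, 1])
    return OutlineContour(
        specimen_id=contour.specimen_id,
        species=contour.species,
        points=np.column_stack([new_x, new_y]),
        closed=True,
        scale=contour.scale,
        scale_defaulted=contour.scale_defaulted,
    )


def _efa_coefficients(
    pts: np.ndarray, n_harmonics: int, parameterization: str
) -> tuple[np.ndarray, np.ndarray]:
    """Raw elliptic Fourier coefficients of the closed polygon.

    Returns ``(offset, coefs)`` with offset the (A0, C0) pair and coefs of
    shape (H, 4).  The integrals are evaluated exactly for the
    piecewise-linear curve.
    """
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)  # (M, 2)
    if parameterization == "chord":
        dt = np.sqrt(np.sum(d**2, axis=1))
    elif parameterization == "uniform":
        dt = np.ones(d.shape[0])
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    big_t = t[-1]

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    phase = 2.0 * np.pi * n * t[None, :] / big_t  # (H, M+1)
    dcos = np.diff(np.cos(phase), axis=1)  # (H, M)
    dsin = np.diff(np.sin(phase), axis=1)
    factor = big_t / (2.0 * n.ravel() ** 2 * np.pi**2)  # (H,)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    coefs = np.column_stack(
        [
            factor * (dcos @ vx),
            factor * (dsin @ vx),
            factor * (dcos @ vy),
            factor * (dsin @ vy),
        ]
    )
    # trapezoid rule is exact for the piecewise-linear x(t), y(t)
    mid = 0.5 * (closed[1:] + closed[:-1])
    offset = (mid * dt[:, None]).sum(axis=0) / big_t
    return offset, coefs


def efa(
    contour: OutlineContour,
    n_harmonics: int = 12,
    parameterization: str = "uniform",
) -> EFADecomposition:
    """Elliptic Fourier decomposition of a closed contour.

    Fewer than ``2 * n_harmonics + 1`` contour points make the highest
    harmonics alias-prone; a warning is logged but the decomposition
    proceeds.
    """
    if n_harmonics < 1:
        raise MorphoIOError("n_harmonics must be >= 1")
    if not contour.closed:
        raise MorphoIOError(
            f"{contour.specimen_id}: EFA requires a closed contour"
        )
    if contour.n_points < 2 * n_harmonics + 1:
        import logging

        logging.getLogger("wingmorph").warning(
            "%s: %d contour points for %d harmonics (recommend >= %d)",
            contour.specimen_id,
            contour.n_points,
            n_harmonics,
            2 * n_harmonics + 1,
        )
    offset, coefs = _efa_coefficients(contour.points, n_harmonics, parameterization)
    return EFADecomposition(
        specimen_id=contour.specimen_id,
        species=contour.species,
        harmonics=coefs,
        offset=offset,
        perimeter=perimeter_length(contour),
        n_harmonics=n_harmonics,
    )


def _phase_rotate(coefs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the curve's starting parameter: harmonic n is rotated in
    parameter space by n * theta."""
    out = np.empty_like(coefs)
    n = np.arange(1, coefs.shape[0] + 1)
    cos_nt = np.cos(n * theta)
    sin_nt = np.sin(n * theta)
    out[:, 0] = coefs[:, 0] * cos_nt + coefs[:, 1] * sin_nt
    out[:, 1] = -coefs[:, 0] * sin_nt + coefs[:, 1] * cos_nt
    out[:, 2] = coefs[:, 2] * cos_nt + coefs[:, 3] * sin_nt
    out[:, 3] = -coefs[:, 2] * sin_nt + coefs[:, 3] * cos_nt
    return out


def _spatial_rotate(coefs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the curve in the plane by -psi."""
    c, s = np.cos(psi), np.sin(psi)
    out = np.empty_like(coefs)
    out[:, 0] = c * coefs[:, 0] + s * coefs[:, 2]
    out[:, 1] = c * coefs[:, 1] + s * coefs[:, 3]
    out[:, 2] = -s * coefs[:, 0] + c * coefs[:, 2]
    out[:, 3] = -s * coefs[:, 1] + c * coefs[:, 3]
    return out


def _normalize_candidate(coefs: np.ndarray, theta: float) -> np.ndarray:
    """Normalize for one choice of the starting-phase angle."""
    rotated = _phase_rotate(coefs, theta)
    a1, _, c1, _ = rotated[0]
    scale = np.hypot(a1, c1)
    psi = np.arctan2(c1, a1)
    return _spatial_rotate(rotated, psi) / scale


def normalize_efa(decomp: EFADecomposition) -> EFADecomposition:
    """Standardize the decomposition for size, rotation and starting point.

    The first-harmonic ellipse defines the normalization: the starting
    phase is shifted to a semi-major axis endpoint, the curve rotated so
    that axis lies along +x, and all coefficients divided by the semi-major
    axis magnitude.  Afterwards a1 = 1 and b1 = c1 = 0; the free
    coefficients (d1 plus all higher harmonics) form the NEF vector of
    length 4H - 3.

    The two semi-major endpoints are both admissible starting phases; the
    tie is broken toward the candidate whose first decisively non-zero
    higher-harmonic coefficient is positive, which keeps the result
    invariant under rotation, scaling, translation and starting-point
    shifts of the input.  The harmonic-1 ellipse must be traced
    counter-clockwise (positive signed area); mirror flips are never
    applied.
    """
    coefs = decomp.harmonics
    a1, b1, c1, d1 = coefs[0]
    # starting-phase angle of the semi-axis (Kuhl & Giardina eq. for theta)
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    # theta may point at the minor axis; take the larger of the two
    probe = _phase_rotate(coefs[:1], theta)[0]
    major = np.hypot(probe[0], probe[2])
    minor = np.hypot(probe[1], probe[3])
    if major < minor:
        theta += 0.5 * np.pi
        probe = _phase_rotate(coefs[:1], theta)[0]
        major = np.hypot(probe[0], probe[2])
    if major <= 0 or not np.isfinite(major):
        raise MorphoIOError(
            f"{decomp.specimen_id}: degenerate first harmonic, cannot normalize"
        )
    cand_a = _normalize_candidate(coefs, theta)
    cand_b = _normalize_candidate(coefs, theta + np.pi)
    if abs(cand_a[0, 3]) < 1e-12:
        raise MorphoIOError(
            f"{decomp.specimen_id}: first-harmonic ellipse has zero area"
        )
    if cand_a[0, 3] < 0:
        raise MorphoIOError(
            f"{decomp.specimen_id}: clockwise harmonic-1 ellipse — orient the "
            "contour counter-clockwise before EFA"
        )
    chosen = cand_a
    if decomp.n_harmonics > 1:
        flat_a = cand_a[1:].ravel()
        flat_b = cand_b[1:].ravel()
        decisive = np.nonzero(np.abs(flat_a - flat_b) > _TIE_EPS)[0]
        if decisive.size and flat_a[decisive[0]] < 0:
            chosen = cand_b
    nef = np.concatenate([[chosen[0, 3]], chosen[1:].ravel()])
    decomp.normalized_harmonics = chosen
    decomp.nef = nef
    return decomp


def reconstruct(
    decomp: EFADecomposition,
    n_points: int = 256,
    n_harmonics: int | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Evaluate the truncated Fourier series on a uniform parameter grid.

    Returns an (n_points, 2) array.  With ``normalized=True`` the
    normalized coefficients are used (unit-size, axis-aligned curve,
    centered at the origin).
    """
    coefs = decomp.normalized_harmonics if normalized else decomp.harmonics
    if coefs is None:
        raise MorphoIOError("normalized coefficients not available")
    h = decomp.n_harmonics if n_harmonics is None else n_harmonics
    coefs = coefs[:h]
    t = np.arange(n_points) / n_points
    n = np.arange(1, coefs.shape[0] + 1)[:, None]
    phase = 2.0 * np.pi * n * t[None, :]
    cos_p, sin_p = np.cos(phase), np.sin(phase)
    x = coefs[:, 0] @ cos_p + coefs[:, 1] @ sin_p
    y = coefs[:, 2] @ cos_p + coefs[:, 3] @ sin_p
    if not normalized:
        x = x + decomp.offset[0]
        y = y + decomp.offset[1]
    return np.column_stack([x, y])
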