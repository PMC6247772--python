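"""Synthetic multi-species wing datasets.

Generates paired landmark configurations (K = 17, the classic mosquito
wing design) and closed outline contours with controlled size
distributions, species mean shapes, allometric size-shape coupling and
digitization noise, so every pipeline stage can be exercised and calibrated
without field specimens.

Species mean shapes are made by deforming one common wing template with
smooth random displacement fields, hierarchically: a large genus-level
deformation shared within each genus and a smaller species-level one on
top.  Trees built from the resulting data therefore have a planted
three-genus clade structure.  The default preset mirrors a seven-species
field collection of 273 mosquitoes across three genera, with per-species
sample sizes and centroid-size means/SDs on a realistic mm scale; the
stylized templates stand in for real vein-intersection landmarks and the
lower wing margin, whose true coordinates are not available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import LandmarkConfiguration, MorphoDataset, OutlineContour, signed_area
from .landmarks import procrustes_distance_pair

__all__ = [
    "SpeciesSpec",
    "SyntheticCollection",
    "make_wing_template",
    "perturb_template",
    "deformation_field",
    "default_species_specs",
    "generate_collection",
]

#: default digitizing resolution, mm per pixel (a 40x scope photograph)
DEFAULT_MM_PER_PX = 0.002

# 17 stylized landmark loci on a wing of unit chord: distributed along the
# leading edge, the crossveins and the posterior margin, as on a real wing.
_LANDMARKS_17 = np.array(
    [
        (0.00, 0.02),
        (0.18, 0.10),
        (0.38, 0.14),
        (0.58, 0.15),
        (0.78, 0.12),
        (0.95, 0.05),
        (1.00, -0.02),
        (0.88, -0.10),
        (0.72, -0.15),
        (0.55, -0.17),
        (0.38, -0.16),
        (0.22, -0.12),
        (0.08, -0.06),
        (0.30, 0.00),
        (0.50, -0.02),
        (0.68, -0.03),
        (0.84, -0.04),
    ]
)


@dataclass
class SpeciesSpec:
    """Generating parameters for one synthetic species."""

    label: str
    n: int
    mean_landmarks: np.ndarray   # (17, 2), unit centroid size
    mean_contour: np.ndarray     # (M, 2), same shape units
    size_mean: float             # mm, centroid-size scale
    size_sd: float               # mm
    shape_sd: float = 0.01       # isotropic per-landmark noise, Procrustes scale
    allometry_coef: float = 0.0  # deformation per mm of size deviation
    contour_noise_sd: float = 0.005  # radial outline noise, shape units

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be >= 1")
        if self.size_mean <= 0:
            raise ValueError(f"{self.label}: size_mean must be > 0")
        if self.size_sd < 0 or self.shape_sd < 0:
            raise ValueError(f"{self.label}: SDs must be >= 0")


@dataclass
class SyntheticCollection:
    landmarks: MorphoDataset
    contours: MorphoDataset
    replicate_landmarks: MorphoDataset | None = None
    replicate_contours: MorphoDataset | None = None
    truth: dict = field(default_factory=dict)


def _unit_cs(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))


def make_wing_template(seed: int = 0, n_contour: int = 96):
    """Common wing template: 17 landmarks and an M-point closed contour.

    The landmark layout is fixed; a small seeded jitter decorrelates
    templates across seeds.  The contour is a smooth wing-like closed
    curve (counter-clockwise, non-self-intersecting), scaled so that its
    perimeter is 1.27 when the landmark configuration has unit centroid
    size — the empirical perimeter-to-centroid-size ratio of mosquito
    wings.
    """
    rng = np.random.default_rng(seed)
    landmarks = _LANDMARKS_17 + rng.normal(0.0, 0.004, _LANDMARKS_17.shape)
    landmarks = _unit_cs(landmarks)

    phi = 2.0 * np.pi * np.arange(n_contour) / n_contour
    x = 0.52 * np.cos(phi) + 0.07 * np.cos(2 * phi) + 0.012 * np.cos(3 * phi)
    y = (
        0.20 * np.sin(phi)
        - 0.05 * np.sin(2 * phi)
        + 0.012 * np.sin(3 * phi)
        - 0.03 * np.cos(phi)
    )
    contour = np.column_stack([x, y])
    contour = contour - contour.mean(axis=0)
    if signed_area(contour) < 0:
        contour = contour[::-1].copy()
    closed = np.vstack([contour, contour[:1]])
    perim = float(np.sqrt(np.sum(np.diff(closed, axis=0) ** 2, axis=1)).sum())
    contour *= 1.27 / perim
    return landmarks, contour


def deformation_field(mode_seed: int, n_centers: int = 6, width: float = 0.35):
    """A smooth random displacement field: a sum of Gaussian bumps with
    random 2-vector weights.  Returns f(points) -> (n, 2) displacements
    with unit root-mean-square magnitude over the landmark template."""
    rng = np.random.default_rng(mode_seed)
    centers = rng.uniform(-0.6, 0.6, size=(n_centers, 2))
    weights = rng.normal(0.0, 1.0, size=(n_centers, 2))

    def raw(points: np.ndarray) -> np.ndarray:
        d2 = np.sum((points[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        return np.exp(-d2 / (2.0 * width**2)) @ weights

    ref = _unit_cs(_LANDMARKS_17)
    norm = np.sqrt(np.mean(np.sum(raw(ref) ** 2, axis=1)))

    def f(points: np.ndarray) -> np.ndarray:
        return raw(points) / norm

    return f


def perturb_template(
    template: np.ndarray, magnitude: float, mode_seed: int
) -> np.ndarray:
    """Deform a template by a smooth random field of the given magnitude.

    ``magnitude`` is approximately the Procrustes distance between the
    template and its deformed copy (exact at magnitude 0); two different
    ``mode_seed`` values deform along different directions.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    template = np.asarray(template, float)
    if magnitude == 0:
        return template.copy()
    f = deformation_field(mode_seed)
    disp = f(template)
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    cs = np.sqrt(np.sum((template - template.mean(axis=0)) ** 2))
    scale = magnitude * cs / (rms * np.sqrt(template.shape[0]))
    return template + scale * disp


def default_species_specs(
    seed: int = 0,
    genus_magnitude: float = 0.06,
    species_magnitude: float = 0.025,
    shape_sd: float = 0.010,
    allometry_coef: float = 0.009,
    contour_noise_sd: float = 0.004,
    orthogonal_species: bool = False,
) -> list[SpeciesSpec]:
    """The standard seven-species, three-genus preset (273 specimens).

    Sample sizes (31, 61, 21, 70, 24, 45, 21) and centroid-size means/SDs
    follow a typical mosquito field collection; genus- and species-level
    mean shapes are hierarchical deformations of one template.
    """
    base_lm, base_ct = make_wing_template(seed)
    # (label, genus index, n, size_mean mm, size_sd mm)
    table = [
        ("An_barbirostris", 0, 31, 3.54, 0.19),
        ("An_subpictus", 0, 61, 2.74, 0.34),
        ("Cx_quinquefasciatus", 1, 21, 2.71, 0.33),
        ("Cx_vishnui", 1, 70, 2.70, 0.26),
        ("Cx_whitmorei", 1, 24, 2.66, 0.11),
        ("Ae_aegypti", 2, 45, 2.19, 0.21),
        ("Ae_albopictus", 2, 21, 2.30, 0.15),
    ]
    ss = np.random.SeedSequence(seed)
    genus_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]

    def _tangent_disps(points, seeds, magnitude, orthogonalize):
        """Smooth displacement fields projected into the shape tangent
        space of ``points`` (similarity components removed — Procrustes
        superimposition would absorb them anyway), optionally made mutually
        orthogonal, each scaled so the planted Procrustes-scale separation
        from the template is ``magnitude``."""
        centered = points - points.mean(axis=0)
        scale = np.sqrt(np.sum(centered**2))
        m = points.shape[0]
        sim = np.column_stack([
            np.tile([1.0, 0.0], m),
            np.tile([0.0, 1.0], m),
            np.column_stack([-centered[:, 1], centered[:, 0]]).ravel(),
            centered.ravel(),
        ])
        sim, _ = np.linalg.qr(sim)
        raw = np.column_stack(
            [deformation_field(s)(points).ravel() for s in seeds]
        )
        raw -= sim @ (sim.T @ raw)
        if orthogonalize:
            raw, _ = np.linalg.qr(raw)
        return [
            magnitude * scale * raw[:, j].reshape(m, 2)
            / np.linalg.norm(raw[:, j])
            for j in range(len(seeds))
        ]

    def _radial_mode(points, k, phase, magnitude):
        """Radial cos(k*phi + phase) deformation of a closed outline.

        Distinct harmonic numbers k map onto distinct elliptic-Fourier
        coefficients, so modes with different k plant separations that
        survive into descriptor space (smooth random fields can collapse
        onto each other there even when orthogonal pointwise)."""
        centered = points - points.mean(axis=0)
        scale = np.sqrt(np.sum(centered**2))
        r = np.linalg.norm(centered, axis=1, keepdims=True)
        radial = centered / np.where(r > 0, r, 1.0)
        phi = np.arctan2(centered[:, 1], centered[:, 0])
        d = radial * np.cos(k * phi + phase)[:, None]
        return magnitude * scale * d / np.linalg.norm(d)

    # genus-level directions are mutually orthogonal per point set: the
    # three genera depart from the common template along independent
    # deformations, planting an unambiguous three-clade truth (raw random
    # fields can correlate by chance and blur it)
    genus_lm = _tangent_disps(base_lm, genus_seeds, genus_magnitude, True)
    genus_ct = [
        _radial_mode(
            base_ct, k, np.random.default_rng(s).uniform(0, 2 * np.pi),
            genus_magnitude,
        )
        for k, s in zip((2, 3, 4), genus_seeds)
    ]

    species_seeds = [
        int(np.random.SeedSequence([seed, 7 + i]).generate_state(1)[0] % 2**31)
        for i in range(len(table))
    ]
    # correlated species directions are the realistic default: wings of
    # congeneric species resemble each other, so some pairs stay hard;
    # orthogonal_species plants fully distinct species means instead
    sp_lm = _tangent_disps(base_lm, species_seeds, species_magnitude,
                           orthogonal_species)
    sp_ct = []
    for i, s in enumerate(species_seeds):
        if orthogonal_species:
            # distinct (harmonic, quadrature) channels: fully separated
            # species means in descriptor space, and low k so the planted
            # signal is not attenuated by resampling and truncation
            k, phase = 5 + i // 2, (i % 2) * np.pi / 2
        else:
            # species within a genus share a harmonic and differ only in
            # phase: congeners stay partially confusable, as in real wings
            k = 5 + table[i][1]  # genus-shared harmonic
            phase = np.random.default_rng(s).uniform(0, 2 * np.pi)
        sp_ct.append(_radial_mode(base_ct, k, phase, species_magnitude))

    specs = []
    for i, (label, genus, n, mu, sd) in enumerate(table):
        lm = base_lm + genus_lm[genus] + sp_lm[i]
        ct = base_ct + genus_ct[genus] + sp_ct[i]
        specs.append(
            SpeciesSpec(
                label=label,
                n=n,
                mean_landmarks=_unit_cs(lm),
                mean_contour=ct - ct.mean(axis=0),
                size_mean=mu,
                size_sd=sd,
                shape_sd=shape_sd,
                allometry_coef=allometry_coef,
                contour_noise_sd=contour_noise_sd,
            )
        )
    return specs


def _truncated_normal(rng, mean, sd, attempts: int = 100) -> float:
    for _ in range(attempts):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise ValueError(
        f"no positive size draw in {attempts} attempts (mean={mean}, sd={sd})"
    )


def generate_collection(
    specs: list[SpeciesSpec],
    seed: int = 0,
    with_replicates: bool = False,
    digitization_sd: float = 0.0,
    mm_per_px: float = DEFAULT_MM_PER_PX,
) -> SyntheticCollection:
    """Generate a paired landmark + contour collection.

    Per specimen: a size is drawn Normal(size_mean, size_sd) truncated
    positive; the landmark shape is the species mean plus the allometric
    deformation scaled by (size - size_mean) plus isotropic Gaussian shape
    noise; the contour shares the same latent allometric deformation and
    adds the same isotropic vertex jitter plus radial outline noise (the
    isotropic term keeps the within-species coefficient covariance
    full-rank, as digitization scatter does on real outlines).  Both are scaled to the drawn size in mm, randomly rotated and
    translated, and expressed in pixels with a per-specimen mm-per-pixel
    factor.  With ``with_replicates``, two independent digitizations are
    produced by adding per-coordinate Gaussian pixel noise of SD
    ``digitization_sd`` to each copy.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    lms, cts, lms_b, cts_b = [], [], [], []
    for si, spec in enumerate(specs):
        f_allo = deformation_field(
            int(np.random.SeedSequence([0xA110, si]).generate_state(1)[0] % 2**31)
        )
        allo_lm = f_allo(spec.mean_landmarks)
        allo_ct = f_allo(spec.mean_contour)
        for i in range(spec.n):
            spec_id = f"{spec.label}:{i:04d}"
            size = _truncated_normal(rng, spec.size_mean, spec.size_sd)
            dsize = size - spec.size_mean
            lm = (
                spec.mean_landmarks
                + spec.allometry_coef * dsize * allo_lm
                + rng.normal(0.0, spec.shape_sd, spec.mean_landmarks.shape)
            )
            ct = (
                spec.mean_contour
                + spec.allometry_coef * dsize * allo_ct
                + rng.normal(0.0, spec.shape_sd, spec.mean_contour.shape)
            )
            if spec.contour_noise_sd > 0:
                radial = ct - ct.mean(axis=0)
                rnorm = np.linalg.norm(radial, axis=1, keepdims=True)
                radial = radial / np.where(rnorm > 0, rnorm, 1.0)
                ct = ct + radial * rng.normal(
                    0.0, spec.contour_noise_sd, (ct.shape[0], 1)
                )
            # express in mm at the drawn centroid size, then in pixels
            lm_mm = _unit_cs(lm) * size
            ct_mm = ct * size
            angle = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(angle), np.sin(angle)
            rot = np.array([[c, -s], [s, c]])
            shift = rng.uniform(500.0, 1500.0, 2)
            px_scale = mm_per_px * (1.0 + rng.uniform(-0.1, 0.1))
            lm_px = (lm_mm @ rot) / px_scale + shift
            ct_px = (ct_mm @ rot) / px_scale + shift
            if signed_area(ct_px) < 0:  # rotation preserves orientation; guard
                ct_px = ct_px[::-1].copy()

            def _noisy(pts):
                if with_replicates and digitization_sd > 0:
                    return pts + rng.normal(0.0, digitization_sd, pts.shape)
                return pts

            lms.append(
                LandmarkConfiguration(spec_id, spec.label, _noisy(lm_px), px_scale)
            )
            cts.append(
                OutlineContour(spec_id, spec.label, _noisy(ct_px), True, px_scale)
            )
            if with_replicates:
                lms_b.append(
                    LandmarkConfiguration(
                        spec_id, spec.label, _noisy(lm_px), px_scale
                    )
                )
                cts_b.append(
                    OutlineContour(
                        spec_id, spec.label, _noisy(ct_px), True, px_scale
                    )
                )
    truth = {
        "seed": seed,
        "digitization_sd": digitization_sd,
        "mm_per_px": mm_per_px,
        "species": [
            {
                "label": s.label,
                "n": s.n,
                "size_mean": s.size_mean,
                "size_sd": s.size_sd,
                "shape_sd": s.shape_sd,
                "allometry_coef": s.allometry_coef,
                "contour_noise_sd": s.contour_noise_sd,
            }
            for s in specs
        ],
    }
    return SyntheticCollection(
        landmarks=MorphoDataset(lms),
        contours=MorphoDataset(cts),
        replicate_landmarks=MorphoDataset(lms_b) if with_replicates else None,
        replicate_contours=MorphoDataset(cts_b) if with_replicates else None,
        truth=truth,
    )


def write_truth(collection: SyntheticCollection, path) -> None:
    """Write the generating parameters as a JSON sidecar."""
    Path(path).write_text(json.dumps(collection.truth, indent=2) + "\n")
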