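# Methods

This note documents the statistical procedures, conventions and design
choices behind wingmorph, and what the synthetic-data tests do and do not
establish about real wing data.

## Landmark shape space

Configurations of K landmarks (K = 17 in the standard mosquito wing
design) are superimposed by Generalised Procrustes Analysis in its
*partial* form: each configuration is centered, scaled to unit centroid
size, and rotated to the consensus; the consensus is the re-normalized
mean of the aligned set, iterated until its Frobenius change falls below
`tol = 1e-10` (at most `max_iter = 100` iterations). Scale is not
re-estimated during the rotation step because centroid size is analyzed as
a separate, biologically meaningful size variable. Reflections are never
allowed: only one wing side is digitized and wings are chiral. After
convergence the consensus is rotated to its principal axes (major axis
along +x, the landmark furthest from the centroid given positive x), which
fixes the otherwise arbitrary orientation of shape space and makes output
reproducible across platforms and input orderings.

**Residual convention.** A specimen's residual is the orthogonal
projection of (aligned − consensus) onto the tangent space at the
consensus, i.e. the component along the unit-norm consensus vector is
removed. Under partial Procrustes the raw deviation retains a
second-order radial term (1 − cos ρ of the Procrustes angle ρ); projecting
it off puts residuals exactly in the 2K − 4 dimensional tangent space, the
same convention as the standard relative-warp tools. For wing-scale
variation (ρ ≲ 0.1) the numerical difference is below 1%.

**Partial warps.** The thin-plate-spline bending-energy matrix of the
consensus (kernel r² log r², upper-left block of the inverted TPS system)
is eigen-decomposed; the K − 3 non-null eigenvectors, copied to x and y,
give 2K − 6 non-affine axes. The two affine (uniform) components are the
orthogonal complement of the non-affine subspace within the tangent space,
oriented deterministically by projecting the symmetric-shear (y, x) and
anisotropic-dilation (x, −y) fields of the consensus onto it (the two
simple shears are congruent modulo rotation, so they span only one
direction). The resulting 2K − 4 basis is an orthonormal rotation of the
residual space: partial-warp scores preserve total residual variance
exactly, and no bending-energy re-weighting is applied (α = 0). The
uniform component is *included* in the shape variables passed to the
discriminant stage, so the full shape variation is analyzed; an
alternative convention restricts to non-affine warps only.

**Relative warps** are covariance-matrix principal components of the
partial-warp scores, with axis signs fixed by the largest loading.
Because the PW basis is orthonormal, RW scores coincide (up to sign) with
principal components of the tangent residuals themselves — a property the
tests exploit as an independent oracle.

## Outline shape space

Closed contours are resampled to equal arc-length spacing
(`resample_points = 100` by default) and decomposed into elliptic Fourier
harmonics: per harmonic n, the quadruple (aₙ, bₙ, cₙ, dₙ) from x(t) and
y(t), with integrals evaluated exactly for the piecewise-linear curve.

**Parameterization.** Vertices are treated as equally spaced in the curve
parameter t. On an equal-arc-length resampled contour this *is*
arc-length parameterization, so for pipeline data the convention coincides
with the classic chord-length weighting (available via
`parameterization="chord"`). The uniform convention is the one under
which an ellipse sampled at uniform phase is exactly a one-harmonic curve
— the closed form the test suite checks. Under chord-length weighting
that closed form is false in the continuum (the arc-length
reparameterization of an ellipse genuinely contains higher harmonics of
magnitude ≈ 0.13 for a 2:1 ellipse), which is worth knowing when comparing
against other EFA implementations.

**Normalization.** The first-harmonic ellipse fixes size (division by its
semi-major axis magnitude), rotation (major axis to +x) and starting phase
(shifted to a semi-major endpoint). Afterwards a₁ = 1, b₁ = c₁ = 0 and
the free vector (d₁ plus harmonics 2..H) has 4H − 3 entries. Two details
matter for invariance:

- the two semi-major endpoints are both admissible phases and flip the
  sign of every even harmonic; the tie is broken toward the candidate
  whose first decisively non-zero higher-harmonic coefficient (|difference|
  > 1e−9) is positive, which is invariant to how the input was rotated,
  scaled or started;
- mirror flips are never applied: the harmonic-1 ellipse must be traced
  counter-clockwise (d₁ > 0); the readers orient raw contours CCW by
  signed area, and a clockwise first harmonic raises an error rather than
  silently reflecting a chiral outline.

Default harmonic count H = 12 (config knob `harmonics`): for wing-like
outlines the reconstruction RMSE at H = 12 is far below digitization
noise, and 4H − 3 = 45 variables remain comfortably below the standard
specimen counts. The analyzed contour is closed; open-arc variants are
out of scope.

## Discrimination

Shape variables can outnumber specimens (45 NEF values, 30 PW scores), so
the discriminant stage first reduces by principal components to the
smallest number of axes explaining ≥ `var_fraction` (default 0.95) of
total variance, hard-capped at n − g so the pooled within-group covariance
is invertible. Canonical axes solve the generalized eigenproblem
S_between v = λ S_pooled v on the reduced space; at most g − 1 axes carry
signal. The Mahalanobis distance between groups is computed from group
means and the pooled covariance on that space.

Classification is by minimal Mahalanobis distance with equal priors —
species prevalences in a trap collection carry no identification
information. Leave-one-out reclassification re-estimates *everything*
(PC reduction, group means, pooled covariance) without the held-out
specimen; distance ties break toward the first species in label order (and
are logged). With ~273 specimens and ≤ 45 variables the n refits cost
well under a second.

## Permutation inference

Pairwise size differences use |mean(a) − mean(b)|; pairwise shape
differences use the two-group Mahalanobis distance, with the PC reduction
fitted on the pooled pair. Labels are permuted within the pair only
(group sizes preserved), matching the pairwise reporting of distances and
sizes; the reduction is label-free and therefore identical under every
permutation, so only means and pooled covariance are recomputed per draw.
The p-value convention is (1 + #{null ≥ observed}) / (1 + n_perm): the
observed statistic is a member of its own reference set and p is never 0.
Bonferroni correction uses m = g(g − 1)/2 (21 for seven species), applied
to the size and shape families separately. Defaults: n_perm = 1000,
α = 0.05, seed 20180611; every report records its config.

Significance letters for the size table are the connected components of
the graph joining species whose adjusted p ≥ α — species sharing a letter
are statistically indistinguishable in mean size.

## Repeatability and allometry

Digitization precision is the one-way-ANOVA intraclass correlation
R = (MS_among − MS_within) / (MS_among + (k − 1) MS_within) over k
replicate digitizations per specimen, truncated to 0 when negative; it is
available both for scalar size variables and per coordinate. Replicates
are averaged before analysis.

Allometry regresses each discriminant factor linearly on size and pools
the per-factor R² weighted by factor variance: the reported percentage is
the fraction of total factor-score variance lying along size. In pooled
multi-species data this measure includes between-species size–shape
confounding (big species with distinctive shapes), not only within-species
growth allometry — the synthetic preset shows 10–20% for this reason even
with weak planted coupling.

## Classification trees

Species are agglomerated on the Mahalanobis matrix by single linkage
(minimum inter-cluster distance) and, as a comparator, UPGMA
(size-weighted average linkage, exact on ultrametric inputs). Both are
direct O(g³) implementations — trivial at g ≤ 7 — with ties in the
minimal linkage distance broken by lexicographic cluster label and logged,
so output is deterministic; scipy's linkage serves as an independent
cross-check in the tests, not as the implementation. Bootstrap support
resamples specimens with replacement *within* each species (B = 100 by
default), recomputes the distance matrix and single-linkage tree, and
scores each original internal node by the fraction of replicate trees
containing the same leaf bipartition (clade content, not heights). Trees
serialize to Newick with supports as internal-node labels and branch
lengths as height differences.

## Synthetic wing collections

The generator defines the conditions every end-to-end test runs under.
The default preset mirrors a seven-species, three-genus field collection:
per-species counts (31, 61, 21, 70, 24, 45, 21; total 273) and
centroid-size means/SDs on the 2.2–3.5 mm scale of real mosquito wings.
Landmark and contour templates are stylized stand-ins (17 fixed loci and a
smooth wing-like closed curve with perimeter 1.27 × CS), since real vein
coordinates are not available.

Species mean shapes are planted hierarchically. Landmark deformations are
smooth Gaussian-bump fields projected into the shape tangent space
(similarity components removed — superimposition would absorb them), with
the three genus-level directions QR-orthogonalized so the three-clade
truth is unambiguous; magnitudes are on the Procrustes-distance scale.
Contour deformations are radial cos(kφ) modes, one harmonic per genus
(k = 2, 3, 4); by default species within a genus share the genus harmonic
and differ only in phase, so congeners stay partially confusable, as real
*Culex* are. With `orthogonal_species=True` each species instead occupies
its own (harmonic, quadrature) channel — the "large planted separations"
regime used by the recovery tests. Radial modes are used for contours
because smooth point-space fields can have nearly parallel elliptic-Fourier
images even when pointwise orthogonal, silently erasing planted structure.

Per specimen: size ~ Normal(μ, σ) truncated positive; landmarks = species
mean + allometric deformation × (size − μ) + isotropic Gaussian noise
(`shape_sd`, Procrustes scale); the contour shares the allometric latent
and the isotropic vertex jitter and adds radial outline noise. Isotropic
contour jitter is essential: purely radial variation is rank-deficient in
coefficient space and makes Mahalanobis distances blow up along
near-zero-variance directions. Shapes are then scaled to the drawn size,
randomly rotated and translated, and expressed in pixels with a
per-specimen mm-per-pixel factor (≈ 0.002, ±10%). Replicate digitizations
add independent iid Gaussian pixel noise to *both* copies — a noise-free
first copy would make the repeatability ANOVA degenerate.

**What the generator does not emulate.** Real digitization error is
correlated along a traced outline, not iid per vertex; with iid noise the
perimeter's error grows with point count, so size and perimeter
repeatability cannot both sit at the 0.97–0.98 level reported for careful
microscope work with a single noise setting (at the default 2 px error the
computed values are ≈ 0.9999 and ≈ 0.997). Wing shape variation is also
not isotropic in nature, venation constrains covariance, and photographs
introduce perspective and mounting distortions none of which are modeled.
Passing recovery tests therefore establishes that the *estimators* are
correct and calibrated under their assumed models, not that real mosquito
species are separable at any particular accuracy.

## Numerical choices and degenerate inputs

- GPA: `tol = 1e-10` (Frobenius change of consensus), `max_iter = 100`;
  non-convergence raises. Coincident landmarks (zero centroid size, or a
  singular TPS kernel in the consensus) raise.
- PC reduction never keeps axes with variance below 1e−12 of the total;
  zero total variance and zero within-group variance raise a
  degenerate-covariance error rather than producing meaningless distances.
- EFA warns (but proceeds) when a contour has fewer than 2H + 1 points;
  normalization raises on a degenerate or clockwise first harmonic.
- All CSV output is written at 6 significant digits; reruns at one seed
  are byte-identical. Every stochastic routine takes an explicit seed, and
  pipeline stages derive their streams from the single config seed.
- Tie rules: nearest-group ties → first label in sorted order; linkage
  ties → lexicographic cluster label; EFA phase ambiguity → first
  decisively positive higher harmonic. All logged where they fire.

## Known limitations

Two-dimensional data only; no sliding semilandmarks or deformation-grid
visualization; no open-arc elliptic Fourier variants; no quadratic or
probabilistic classification; Bonferroni only (no FDR). The pipeline
assumes one consistent digitization convention per dataset (landmark order
and y-axis direction); datasets mixing conventions will superimpose as if
mirrored.
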