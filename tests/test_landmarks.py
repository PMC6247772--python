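import numpy as np
import pytest

import wingmorph as wm
from wingmorph.io import LandmarkConfiguration as LC, MorphoDataset as MD
from wingmorph.landmarks import GPAError

from conftest import random_similarity


def _cfg(coords, scale=1.0, sid="s", species="sp"):
    return LC(sid, species, np.asarray(coords, float), scale)


class TestCentroidSize:
    def test_unit_square_analytic(self):
        cs = wm.centroid_size(_cfg([(1, 1), (1, -1), (-1, 1), (-1, -1)]))
        assert cs == pytest.approx(np.sqrt(8), abs=1e-12)

    def test_translation_invariance(self, rng):
        coords = rng.normal(size=(17, 2))
        a = wm.centroid_size(_cfg(coords))
        b = wm.centroid_size(_cfg(coords + [10, -3]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_homogeneity_and_scale_factor(self, rng):
        coords = rng.normal(size=(17, 2))
        assert wm.centroid_size(_cfg(coords * 2)) == pytest.approx(
            2 * wm.centroid_size(_cfg(coords)), rel=1e-12
        )
        assert wm.centroid_size(_cfg(coords, scale=0.01)) == pytest.approx(
            0.01 * wm.centroid_size(_cfg(coords)), rel=1e-12
        )

    def test_coincident_points_error(self):
        with pytest.raises(GPAError, match="coincide"):
            wm.centroid_size(_cfg([(1, 1), (1, 1), (1, 1)]))


class TestGPA:
    def test_exact_alignability_of_one_shape(self, rng):
        base = rng.normal(size=(17, 2))
        recs = []
        for i in range(8):
            rot, sc, tr = random_similarity(rng)
            recs.append(_cfg(base @ rot * sc + tr, sid=f"s{i}"))
        fit = wm.gpa(MD(recs))
        assert np.abs(fit.aligned - fit.mean_shape).max() < 1e-8
        assert np.sum(fit.residuals**2) < 1e-12

    def test_consensus_normalization(self, rng):
        recs = [_cfg(rng.normal(size=(5, 2)), sid=f"t{i}") for i in range(2)]
        fit = wm.gpa(MD(recs))
        np.testing.assert_allclose(fit.mean_shape.mean(axis=0), 0, atol=1e-12)
        assert np.sum(fit.mean_shape**2) == pytest.approx(1.0, abs=1e-12)

    def test_two_shape_distance_matches_closed_form(self, rng):
        """GPA-derived pairwise distance equals the direct two-shape
        ordinary Procrustes solution (SVD closed form)."""
        for _ in range(50):
            a, b = rng.normal(size=(17, 2)), rng.normal(size=(17, 2))
            fit = wm.gpa(MD([_cfg(a, sid="a"), _cfg(b, sid="b")]))
            assert fit.procrustes_distance(0, 1) == pytest.approx(
                wm.procrustes_distance_pair(a, b), abs=1e-8
            )

    def test_residuals_sum_to_zero_per_specimen(self, rng):
        base = rng.normal(size=(10, 2))
        recs = [_cfg(base + rng.normal(0, 0.05, (10, 2)), sid=f"s{i}") for i in range(6)]
        fit = wm.gpa(MD(recs))
        np.testing.assert_allclose(
            fit.residuals.sum(axis=1), 0, atol=1e-10
        )

    def test_k_mismatch_error(self, rng):
        recs = [_cfg(rng.normal(size=(5, 2))),
                LC("s2", "sp", rng.normal(size=(6, 2)), 1.0)]
        with pytest.raises(GPAError, match="mismatch"):
            wm.gpa(MD(recs))

    def test_single_specimen_error(self, rng):
        with pytest.raises(GPAError, match="2 specimens"):
            wm.gpa(MD([_cfg(rng.normal(size=(5, 2)))]))

    def test_shape_variables_invariant_under_rigid_motion(self, rng):
        """CS and Procrustes shape variables must not change when every raw
        configuration is rotated/translated (and CS scales linearly under
        isotropic scaling)."""
        base = rng.normal(size=(17, 2))
        coords = [base + rng.normal(0, 0.03, (17, 2)) for _ in range(8)]
        fit0 = wm.gpa(MD([_cfg(c, sid=f"s{i}") for i, c in enumerate(coords)]))
        wm.partial_warps(fit0)
        for trial in range(5):
            rot, sc, tr = random_similarity(rng)
            recs = [_cfg(c @ rot * sc + tr, sid=f"s{i}") for i, c in enumerate(coords)]
            fit1 = wm.gpa(MD(recs))
            wm.partial_warps(fit1)
            np.testing.assert_allclose(
                fit1.centroid_sizes, sc * fit0.centroid_sizes, rtol=1e-8
            )
            np.testing.assert_allclose(fit1.pw_scores, fit0.pw_scores, atol=1e-8)

    def test_distances_invariant_to_input_order(self, rng):
        base = rng.normal(size=(8, 2))
        coords = [base + rng.normal(0, 0.05, (8, 2)) for _ in range(6)]
        fit = wm.gpa(MD([_cfg(c, sid=f"s{i}") for i, c in enumerate(coords)]))
        perm = rng.permutation(6)
        fit_p = wm.gpa(MD([_cfg(coords[j], sid=f"s{j}") for j in perm]))
        for a in range(6):
            for b in range(a + 1, 6):
                pa, pb = int(np.where(perm == a)[0][0]), int(np.where(perm == b)[0][0])
                assert fit.procrustes_distance(a, b) == pytest.approx(
                    fit_p.procrustes_distance(pa, pb), abs=1e-8
                )


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(99)
    base = rng.normal(size=(17, 2))
    recs = [_cfg(base + rng.normal(0, 0.04, (17, 2)), sid=f"s{i}")
            for i in range(12)]
    f = wm.gpa(MD(recs))
    wm.partial_warps(f)
    return f


class TestPartialWarps:

    def test_dimensionality_2k_minus_4(self, fit):
        assert fit.pw_scores.shape[1] == 2 * 17 - 4

    @pytest.mark.parametrize("k", [5, 9, 17])
    def test_dimensionality_other_k(self, k):
        rng = np.random.default_rng(k)
        base = rng.normal(size=(k, 2))
        recs = [_cfg(base + rng.normal(0, 0.03, (k, 2)), sid=f"s{i}")
                for i in range(6)]
        f = wm.gpa(MD(recs))
        assert wm.partial_warps(f).shape[1] == 2 * k - 4

    def test_orthonormality_preserves_sum_of_squares(self, fit):
        ss_pw = np.sum(fit.pw_scores**2)
        ss_res = np.sum(fit.residuals**2)
        assert abs(ss_pw - ss_res) / ss_res < 1e-10

    def test_specimen_identical_to_consensus_scores_zero(self, rng):
        """When every specimen is a similarity copy of one shape, all equal
        the consensus after alignment and every PW vector is zero."""
        base = rng.normal(size=(17, 2))
        recs = []
        for i in range(5):
            rot, sc, tr = random_similarity(rng)
            recs.append(_cfg(base @ rot * sc + tr, sid=f"s{i}"))
        f = wm.gpa(MD(recs))
        pw = wm.partial_warps(f)
        assert np.abs(pw).max() < 1e-8

    def test_coincident_consensus_landmarks_error(self):
        mean = np.array([[0.5, 0.0], [0.5, 0.0], [-0.5, 0.0], [0.0, 0.5]])
        with pytest.raises(GPAError, match="coincident"):
            wm.landmarks.pw_basis(mean / np.linalg.norm(mean))


class TestRelativeWarps:
    def test_equivalence_with_residual_pca(self, rng):
        """RW scores equal (up to per-axis sign) the PCA scores of the raw
        tangent residual matrix — an independent equivalence oracle."""
        base = rng.normal(size=(10, 2))
        recs = [_cfg(base + rng.normal(0, 0.05, (10, 2)), sid=f"s{i}")
                for i in range(9)]
        fit = wm.gpa(MD(recs))
        rw, explained = wm.relative_warps(fit)
        flat = fit.residuals.reshape(len(recs), -1)
        flat = flat - flat.mean(axis=0)
        _, s, vt = np.linalg.svd(flat, full_matrices=False)
        direct = flat @ vt.T
        r = min(rw.shape[1], direct.shape[1], 6)
        np.testing.assert_allclose(
            np.abs(rw[:, :r]), np.abs(direct[:, :r]), atol=1e-8
        )

    def test_explained_variance_sums_to_one_nonincreasing(self, rng):
        base = rng.normal(size=(6, 2))
        recs = [_cfg(base + rng.normal(0, 0.05, (6, 2)), sid=f"s{i}")
                for i in range(8)]
        fit = wm.gpa(MD(recs))
        _, explained = wm.relative_warps(fit)
        assert explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_planted_deformation_axis_separates_groups(self):
        """Two groups deformed in opposite directions along one smooth mode
        must separate on RW1."""
        base, _ = wm.make_wing_template(0)
        field = wm.synthetic.deformation_field(77)(base)
        rng = np.random.default_rng(4)
        recs = []
        for i in range(10):
            sign = 1.0 if i < 5 else -1.0
            coords = base + 0.08 * sign * field + rng.normal(0, 0.005, base.shape)
            recs.append(_cfg(coords, sid=f"s{i}"))
        fit = wm.gpa(MD(recs))
        rw, _ = wm.relative_warps(fit)
        g1, g2 = rw[:5, 0], rw[5:, 0]
        assert max(g1.min(), g2.min()) > min(g1.max(), g2.max()) or \
            max(g2.min(), g1.min()) > min(g2.max(), g1.max())
        # complete separation on RW1
        assert (g1.min() > g2.max()) or (g2.min() > g1.max())
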