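import numpy as np
import pytest

import wingmorph as wm


class TestPermTestSize:
    def test_complete_separation_gives_minimum_p(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        labels = np.repeat(["a", "b"], 20)
        r = wm.perm_test_size(vals, labels, "a", "b", n_perm=1000, seed=3)
        assert r.p_raw == pytest.approx(1 / 1001)

    def test_identical_constant_values_give_p_one(self):
        vals = np.ones(20)
        labels = np.repeat(["a", "b"], 10)
        r = wm.perm_test_size(vals, labels, "a", "b", n_perm=99, seed=1)
        assert r.p_raw == 1.0

    def test_symmetric_in_group_roles(self, rng):
        vals = rng.normal(size=30)
        labels = np.repeat(["a", "b"], 15)
        pa = wm.perm_test_size(vals, labels, "a", "b", n_perm=199, seed=7).p_raw
        pb = wm.perm_test_size(vals, labels, "b", "a", n_perm=199, seed=7).p_raw
        assert pa == pb

    def test_seed_reproducibility(self, rng):
        vals = rng.normal(size=24)
        labels = np.repeat(["a", "b"], 12)
        r1 = wm.perm_test_size(vals, labels, "a", "b", n_perm=99, seed=5)
        r2 = wm.perm_test_size(vals, labels, "a", "b", n_perm=99, seed=5)
        np.testing.assert_array_equal(r1.null_stats, r2.null_stats)
        assert r1.p_raw == r2.p_raw

    def test_empty_group_error(self, rng):
        with pytest.raises(ValueError, match="empty"):
            wm.perm_test_size(np.ones(3), ["a"] * 3, "a", "b")


class TestPermTestShape:
    def test_planted_shift_gives_minimum_p(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(4, 1, (20, 3))])
        labels = np.repeat(["a", "b"], 20)
        r = wm.perm_test_shape(x, labels, "a", "b", n_perm=1000, seed=2)
        assert r.p_raw == pytest.approx(1 / 1001)

    def test_p_bounded_below_by_reference_set_convention(self, rng):
        x = rng.normal(size=(20, 3))
        labels = np.repeat(["a", "b"], 10)
        r = wm.perm_test_shape(x, labels, "a", "b", n_perm=49, seed=1)
        assert r.p_raw >= 1 / 50

    def test_symmetric_in_group_roles(self, rng):
        x = rng.normal(size=(24, 3))
        labels = np.repeat(["a", "b"], 12)
        pa = wm.perm_test_shape(x, labels, "a", "b", n_perm=99, seed=9).p_raw
        pb = wm.perm_test_shape(x, labels, "b", "a", n_perm=99, seed=9).p_raw
        assert pa == pb

    def test_observed_statistic_matches_pairwise_model_d(self, rng):
        x = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(1, 1, (15, 4))])
        labels = np.repeat(["a", "b"], 15)
        r = wm.perm_test_shape(x, labels, "a", "b", n_perm=9, seed=0,
                               var_fraction=1.0)
        model = wm.fit_da(x, labels, var_fraction=1.0)
        assert r.observed == pytest.approx(model.mahalanobis[0, 1], abs=1e-8)


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        out = wm.bonferroni([0.002, 0.5, 0.04], m=21)
        np.testing.assert_allclose(out, [0.042, 1.0, 0.84])

    def test_m_one_is_identity(self):
        np.testing.assert_allclose(wm.bonferroni([0.3, 0.9], 1), [0.3, 0.9])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            wm.bonferroni([0.0, 0.5], 2)
        with pytest.raises(ValueError):
            wm.bonferroni([1.5], 2)


class TestRepeatability:
    def test_identical_replicates_give_r_one(self, rng):
        truth = rng.normal(size=20)
        r = wm.repeatability(np.column_stack([truth, truth]))
        assert r.r == pytest.approx(1.0)

    def test_parameter_recovery_icc_09(self):
        """Planted among/within variances 9 and 1 (ICC = 0.9) recovered
        within +/- 0.03 at n = 500, k = 2."""
        rng = np.random.default_rng(13)
        truth = rng.normal(0, 3.0, 500)
        x = truth[:, None] + rng.normal(0, 1.0, (500, 2))
        r = wm.repeatability(x)
        assert abs(r.r - 0.9) < 0.03

    @pytest.mark.parametrize("n,tol", [(50, 0.12), (500, 0.035), (5000, 0.012)])
    def test_convergence_to_true_icc(self, n, tol):
        rng = np.random.default_rng(n)
        icc = 0.8
        truth = rng.normal(0, np.sqrt(icc), n)
        x = truth[:, None] + rng.normal(0, np.sqrt(1 - icc), (n, 2))
        assert abs(wm.repeatability(x).r - icc) < tol

    def test_all_identical_error(self):
        with pytest.raises(ValueError, match="identical"):
            wm.repeatability(np.ones((10, 2)))

    def test_negative_estimate_truncated_to_zero(self, rng):
        # within-noise dominates: point estimate can go negative
        x = rng.normal(0, 1, (5, 2))
        r = wm.repeatability(x)
        assert r.r >= 0.0

    def test_per_coordinate_repeatability(self, rng):
        from wingmorph.stats import coordinate_repeatability

        truth = rng.normal(0, 3, (100, 5, 2))
        a = truth + rng.normal(0, 0.3, truth.shape)
        b = truth + rng.normal(0, 0.3, truth.shape)
        rs = coordinate_repeatability(a, b)
        assert rs.shape == (5, 2)
        assert np.all(rs > 0.9)


class TestAllometry:
    def test_independent_scores_explain_under_two_percent(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=(500, 3))
        sizes = rng.normal(3, 0.3, 500)
        res = wm.allometry(scores, sizes)
        assert res.r2_percent < 2.0

    def test_exact_linear_factor_gives_100(self, rng):
        sizes = rng.normal(3, 0.4, 50)
        scores = (0.5 * sizes)[:, None]
        res = wm.allometry(scores, sizes)
        assert res.r2_percent == pytest.approx(100.0, abs=1e-8)

    def test_correlation_sign_matches_planted_slope(self, rng):
        sizes = rng.normal(3, 0.4, 100)
        scores = np.column_stack(
            [2.0 * sizes + rng.normal(0, 0.1, 100),
             -1.5 * sizes + rng.normal(0, 0.1, 100)]
        )
        res = wm.allometry(scores, sizes)
        assert res.correlations[0] > 0 > res.correlations[1]
        assert res.slopes[0] > 0 > res.slopes[1]

    def test_constant_sizes_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            wm.allometry(rng.normal(size=(10, 2)), np.ones(10))


class TestQuantileSummary:
    def test_linear_interpolation_convention(self):
        df = wm.quantile_summary(np.array([1, 2, 3, 4, 5.0]), ["s"] * 5)
        assert df.loc["s", "p25"] == 2.0
        assert df.loc["s", "median"] == 3.0
        assert df.loc["s", "p75"] == 4.0

    def test_single_value_all_quantiles_equal(self):
        df = wm.quantile_summary(np.array([7.0]), ["s"])
        assert df.loc["s", ["min", "p25", "median", "p75", "max"]].eq(7.0).all()

    def test_seven_species_rows_on_default_preset(self, default_collection):
        sizes = np.array(
            [wm.centroid_size(r) for r in default_collection.landmarks]
        )
        labels = [r.species for r in default_collection.landmarks]
        df = wm.quantile_summary(sizes, labels)
        assert len(df) == 7
        assert df["n"].sum() == 273


class TestSignificanceLetters:
    def test_connected_components_share_letters(self):
        from wingmorph.stats import significance_letters

        labels = ["a", "b", "c"]
        # a-b not significant (joined), c significant vs both
        p = {
            frozenset(("a", "b")): 0.8,
            frozenset(("a", "c")): 0.001,
            frozenset(("b", "c")): 0.001,
        }
        letters = significance_letters(labels, p, alpha=0.05)
        assert letters["a"] == letters["b"] != letters["c"]
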