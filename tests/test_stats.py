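import numpy as np
import pytest
from scipy import stats as sps

from morphoqtl.stats import (
    DiscriminantModel,
    classify,
    hotelling_power,
    hotelling_t2,
    lda_fit,
    lda_score,
    loocv_rate,
    mahalanobis_d2,
    n_components_for_variance,
    pca_fit,
    size_shape_regression,
    size_table_and_anova,
)
from morphoqtl.tps import Outline


class TestPCA:
    def test_planar_data_two_components_full_variance(self, rng):
        basis = rng.normal(size=(2, 120))
        X = rng.normal(size=(30, 2)) @ basis
        space = pca_fit(X, 2)
        assert space.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_variance_fractions_non_increasing(self, rng):
        X = rng.normal(size=(40, 10)) * np.arange(1, 11)
        space = pca_fit(X)
        assert np.all(np.diff(space.variance_fraction) <= 1e-12)

    def test_rank_exceeded_names_achievable_rank(self, rng):
        X = np.tile(rng.normal(size=(1, 6)), (10, 1)) + np.outer(
            rng.normal(size=10), rng.normal(size=6)
        )
        with pytest.raises(ValueError, match="rank is 1"):
            pca_fit(X, 5)

    def test_scores_reproduce_centered_data(self, rng):
        X = rng.normal(size=(25, 8))
        space = pca_fit(X)
        rec = space.scores @ space.loadings + space.mean
        np.testing.assert_allclose(rec, X, atol=1e-10)

    def test_transform_matches_training_scores(self, rng):
        X = rng.normal(size=(25, 8))
        space = pca_fit(X, 4)
        np.testing.assert_allclose(space.transform(X), space.scores, atol=1e-10)

    def test_components_for_variance_rule(self, rng):
        X = rng.normal(size=(50, 10)) * np.array([10, 5, 2, 1, 0.5, 0.2] + [0.01] * 4)
        k = n_components_for_variance(X, 0.99)
        space = pca_fit(X)
        cum = np.cumsum(space.variance_fraction)
        assert cum[k - 1] >= 0.99 and (k == 1 or cum[k - 2] < 0.99)


class TestLDA:
    def test_two_groups_single_axis(self, rng):
        X = rng.normal(size=(40, 5))
        labels = np.repeat(["a", "b"], 20)
        model = lda_fit(X, labels)
        assert model.n_axes == 1

    def test_axis_recovers_separation_direction(self, rng):
        X = rng.normal(size=(1000, 5))
        X[500:, 0] += 4.0
        labels = np.repeat(["a", "b"], 500)
        model = lda_fit(X, labels)
        w = model.axes[:, 0]
        cosine = abs(w[0]) / np.linalg.norm(w)
        assert cosine > 0.99

    def test_relabeled_identical_groups_no_separation(self, rng):
        X = np.vstack([rng.normal(size=(20, 4))] * 2)
        labels = np.repeat(["a", "b"], 20)
        model = lda_fit(X, labels)
        # group means coincide, canonical separation collapses
        assert np.abs(model.group_means).max() < 1e-8

    def test_matches_sklearn_direction(self, rng):
        """Independent cross-check of the canonical axis against sklearn's
        eigen-solver discriminant (same subspace up to sign/scale)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(90, 6))
        X[30:60, 1] += 2.0
        X[60:, 2] -= 1.5
        labels = np.repeat(["a", "b", "c"], 30)
        model = lda_fit(X, labels)
        sk = LinearDiscriminantAnalysis(solver="eigen").fit(X, labels)
        for k in range(2):
            w, v = model.axes[:, k], sk.scalings_[:, k]
            cosine = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
            assert cosine > 0.999

    def test_orientation_reference_group_positive(self, rng):
        X = rng.normal(size=(40, 3))
        X[:20, 0] -= 3.0  # group 'ref' on the negative side initially
        labels = np.repeat(["ref", "other"], 20)
        model = lda_fit(X, labels, positive_group="ref")
        assert model.group_means[model.groups.index("ref"), 0] > 0

    def test_score_linearity_grand_mean_midway(self, rng):
        X = rng.normal(size=(40, 3))
        X[20:, 0] += 2.0
        labels = np.repeat(["a", "b"], 20)
        model = lda_fit(X, labels, positive_group="a")
        mid = lda_score(model, X.mean(0, keepdims=True))[0]
        means = [
            lda_score(model, X[labels == g].mean(0, keepdims=True))[0]
            for g in ("a", "b")
        ]
        assert mid == pytest.approx(np.mean(means), abs=1e-10)

    def test_multi_axis_requires_explicit_choice(self, rng):
        X = rng.normal(size=(60, 4))
        labels = np.repeat(["a", "b", "c"], 20)
        model = lda_fit(X, labels)
        with pytest.raises(ValueError, match="axes"):
            lda_score(model, X)
        assert lda_score(model, X, axis=1).shape == (60,)

    def test_axis_invariant_to_linear_reparameterization(self, rng):
        """The discriminant score is unchanged (up to sign) under any
        invertible linear transform of the PC basis."""
        X = rng.normal(size=(50, 4))
        X[25:, 0] += 3.0
        labels = np.repeat(["a", "b"], 25)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        s1 = lda_score(lda_fit(X, labels, positive_group="a"), X)
        s2 = lda_score(lda_fit(X @ A, labels, positive_group="a"), X @ A)
        np.testing.assert_allclose(s1, s2, atol=1e-8)


class TestLOOCV:
    def test_well_separated_groups_classified_perfectly(self, rng):
        X = rng.normal(size=(30, 3))
        X[15:, 0] += 10.0
        labels = np.repeat(["a", "b"], 15)
        rate, table = loocv_rate(X, labels)
        assert rate == 100.0
        assert table.loc["a", "b"] == 0

    def test_permuted_labels_near_chance(self, rng):
        rates = []
        for _ in range(20):
            X = rng.normal(size=(24, 3))
            labels = rng.permutation(np.repeat(["a", "b"], 12))
            rates.append(loocv_rate(X, labels)[0])
        assert 35 < np.mean(rates) < 65

    def test_exact_ties_break_toward_lower_sort_order(self):
        model = DiscriminantModel(
            groups=["a", "b"],
            axes=np.eye(2),
            axis_variance_fraction=np.array([1.0]),
            group_means=np.array([[1.0, 0.0], [-1.0, 0.0]]),
            pooled_cov=np.eye(2),
            grand_mean=np.zeros(2),
        )
        # the origin is exactly equidistant from both group means
        assert classify(model, np.zeros((1, 2))) == ["a"]

    def test_fully_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="singular|fewer"):
            loocv_rate(np.zeros((6, 2)), np.repeat(["a", "b"], 3))

    def test_not_worse_than_resubstitution_on_average(self, rng):
        diffs = []
        for _ in range(15):
            X = rng.normal(size=(30, 4))
            X[15:, 0] += 1.0
            labels = np.repeat(["a", "b"], 15)
            model = lda_fit(X, labels)
            resub = np.mean(np.array(classify(model, X)) == labels) * 100
            cv, _ = loocv_rate(X, labels)
            diffs.append(resub - cv)
        assert np.mean(diffs) >= 0.0

    def test_small_group_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match=">= 3"):
            loocv_rate(X, np.array(["a", "a", "a", "b", "b"]))


class TestHotelling:
    def test_identical_groups_zero_statistic(self, rng):
        X = rng.normal(size=(15, 3))
        res = hotelling_t2(X, X.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-20)
        assert res.p_raw == pytest.approx(1.0)

    def test_univariate_hand_oracle(self):
        res = hotelling_t2([0.0, 1.0, 2.0], [3.0, 4.0, 5.0])
        assert res.d2 == pytest.approx(9.0)
        assert res.t2 == pytest.approx(13.5)
        assert res.f == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_affine_invariance(self, rng):
        X1, X2 = rng.normal(size=(12, 3)), rng.normal(size=(14, 3)) + 0.5
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        base = hotelling_t2(X1, X2)
        moved = hotelling_t2(X1 @ A + b, X2 @ A + b)
        assert moved.t2 == pytest.approx(base.t2, rel=1e-9)

    def test_group_count_df_convention(self, rng):
        X1, X2 = rng.normal(size=(20, 3)), rng.normal(size=(22, 3))
        res = hotelling_t2(X1, X2, df_convention="groups", n_groups=5)
        assert res.df == (5, 20 + 22 - 5 - 1)

    def test_bonferroni_capped(self, rng):
        X1, X2 = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        res = hotelling_t2(X1, X2, n_comparisons=50)
        assert res.p_bonferroni <= 1.0
        assert res.p_bonferroni >= res.p_raw

    def test_mahalanobis_override_covariance(self, rng):
        X1, X2 = rng.normal(size=(10, 2)), rng.normal(size=(10, 2)) + 1
        d_id = mahalanobis_d2(X1, X2, cov=np.eye(2))
        diff = X1.mean(0) - X2.mean(0)
        assert d_id == pytest.approx(float(diff @ diff))


class TestPower:
    def test_zero_effect_power_equals_alpha(self):
        assert hotelling_power(0.0, 20, 20, 3, alpha=0.05) == pytest.approx(0.05)

    def test_large_effect_power_approaches_one(self):
        assert hotelling_power(1e6, 20, 20, 3) > 0.9999

    def test_monotone_in_noncentrality(self):
        lam = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        powers = [hotelling_power(x, 20, 20, 3) for x in lam]
        assert np.all(np.diff(powers) > 0)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            hotelling_power(1.0, 2, 2, 5)


def square(scale, n=12):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = scale * np.c_[np.cos(t), np.sin(t)]
    return Outline(pts, pts[[0, 3, 6, 9]], "s")


class TestSizeAnalyses:
    def test_identical_specimens_f_zero(self):
        outs = [square(1.0) for _ in range(12)]
        res = size_table_and_anova(outs, np.repeat(["a", "b"], 6))
        assert res["anova_f"] == 0.0

    def test_scaled_group_detected(self, rng):
        outs, groups = [], []
        for g, scale in (("a", 1.0), ("b", 1.1)):
            for _ in range(20):
                outs.append(square(scale * (1 + 0.01 * rng.standard_normal())))
                groups.append(g)
        res = size_table_and_anova(outs, np.array(groups))
        tab = res["table"].set_index("group")
        assert tab.loc["b", "mean"] / tab.loc["a", "mean"] == pytest.approx(1.1, abs=0.02)
        assert res["anova_p"] < 1e-6
        assert list(res["table"].columns) == ["group", "n", "mean", "sem"]

    def test_singleton_group_excluded_from_pairwise(self, rng):
        outs = [square(1 + 0.01 * rng.standard_normal()) for _ in range(9)]
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"])
        with pytest.warns(UserWarning, match="size 1"):
            res = size_table_and_anova(outs, groups)
        assert set(res["pairwise"]["group_a"]) | set(res["pairwise"]["group_b"]) == {
            "a",
            "b",
        }

    def test_size_driven_component_detected(self, rng):
        sizes = rng.uniform(1, 2, size=60)
        pcs = np.column_stack(
            [3 * sizes + 0.01 * rng.standard_normal(60), rng.normal(size=(60,))]
        )
        res = size_shape_regression(pcs, sizes)
        row = res["per_component"].iloc[0]
        assert row["R2"] > 0.99 and row["p_raw"] < 1e-10
        assert res["omnibus_p"] < 1e-10

    def test_df_exhaustion_rejected(self, rng):
        with pytest.raises(ValueError, match="n > K"):
            size_shape_regression(rng.normal(size=(6, 5)), rng.uniform(1, 2, 6))

    def test_constant_size_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            size_shape_regression(rng.normal(size=(10, 2)), np.ones(10))
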