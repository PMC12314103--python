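import numpy as np
import pandas as pd
import pytest

from microskill import (
    CohortTable,
    InputError,
    ParameterKey,
    discriminant_score,
    fit_lda,
    pairwise_auc,
    roc_auc,
)


def brute_force_auc(scores, labels):
    """Mean over all (good, poor) pairs of win indicator, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == "good"]
    neg = [s for s, l in zip(scores, labels) if l == "poor"]
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def cohort_from(values: np.ndarray, labels, features):
    df = pd.DataFrame(values, columns=[k.label for k in features],
                      index=[f"s{i}" for i in range(len(values))])
    return CohortTable(values=df, labels=pd.Series(labels, index=df.index))


F1 = ParameterKey("pd", hand="right", phase="All")
F2 = ParameterKey("nji", hand="left", phase="All")


class TestFitLda:
    def test_axis_aligned_separation_ignores_other_feature(self, rng):
        n = 40
        x1 = np.concatenate([rng.normal(3, 1, n), rng.normal(-3, 1, n)])
        x2 = rng.normal(0, 1, 2 * n)
        labels = ["good"] * n + ["poor"] * n
        cohort = cohort_from(np.column_stack([x1, x2]), labels, [F1, F2])
        model = fit_lda(cohort, [F1, F2])
        assert abs(model.weights[1]) < 0.2 * abs(model.weights[0])

    def test_one_dimensional_closed_form(self, rng):
        good = rng.normal(2, 1, 10)
        poor = rng.normal(0, 1, 12)
        cohort = cohort_from(
            np.concatenate([good, poor])[:, None],
            ["good"] * 10 + ["poor"] * 12, [F1],
        )
        model = fit_lda(cohort, [F1])
        pooled = ((len(good) - 1) * good.var(ddof=1)
                  + (len(poor) - 1) * poor.var(ddof=1)) / (10 + 12 - 2)
        assert model.weights[0] == pytest.approx(
            (good.mean() - poor.mean()) / pooled
        )

    def test_duplicated_feature_ridge_fallback(self, rng):
        x = np.concatenate([rng.normal(2, 1, 8), rng.normal(0, 1, 8)])
        labels = ["good"] * 8 + ["poor"] * 8
        single = cohort_from(x[:, None], labels, [F1])
        doubled = cohort_from(np.column_stack([x, x]), labels, [F1, F2])
        s1 = discriminant_score(fit_lda(single, [F1]), single)
        s2 = discriminant_score(fit_lda(doubled, [F1, F2]), doubled)
        # identical ROC ordering despite the singular covariance
        assert pairwise_auc(s2.values, np.array(labels)) == pytest.approx(
            pairwise_auc(s1.values, np.array(labels)), abs=1e-6
        )

    def test_one_class_missing_rejected(self, rng):
        cohort = cohort_from(rng.normal(size=(5, 1)), ["good"] * 5, [F1])
        with pytest.raises(InputError):
            fit_lda(cohort, [F1])

    def test_recovers_population_direction(self, rng):
        # within-class Gaussian with known covariance: fitted weights align
        # with Sigma^-1 (mu_g - mu_p)
        sigma = np.array([[2.0, 0.8], [0.8, 1.0]])
        delta = np.array([1.5, -0.5])
        chol = np.linalg.cholesky(sigma)
        n = 400
        xg = rng.normal(size=(n, 2)) @ chol.T + delta
        xp = rng.normal(size=(n, 2)) @ chol.T
        cohort = cohort_from(
            np.vstack([xg, xp]), ["good"] * n + ["poor"] * n, [F1, F2]
        )
        w = fit_lda(cohort, [F1, F2]).weights
        target = np.linalg.solve(sigma, delta)
        cos = w @ target / np.linalg.norm(w) / np.linalg.norm(target)
        assert cos > 0.99


class TestDiscriminantScore:
    def test_good_mean_scores_above_poor_mean(self, rng):
        x = np.concatenate([rng.normal(1, 1, 10), rng.normal(-1, 1, 10)])
        labels = ["good"] * 10 + ["poor"] * 10
        cohort = cohort_from(x[:, None], labels, [F1])
        model = fit_lda(cohort, [F1])
        mu_g = model.class_means["good"]
        mu_p = model.class_means["poor"]
        assert model.weights @ mu_g > model.weights @ mu_p

    def test_affine_feature_rescaling_preserves_roc(self, rng):
        n = 24
        x = rng.normal(size=(n, 2)) + np.array([[1.0, 0.5]]) * (
            np.arange(n) < n // 2
        )[:, None]
        labels = ["good"] * (n // 2) + ["poor"] * (n // 2)
        c1 = cohort_from(x, labels, [F1, F2])
        a = x @ np.array([[2.0, 0.3], [-0.5, 1.5]]) + np.array([10.0, -4.0])
        c2 = cohort_from(a, labels, [F1, F2])
        s1 = discriminant_score(fit_lda(c1, [F1, F2]), c1)
        s2 = discriminant_score(fit_lda(c2, [F1, F2]), c2)
        labels = np.array(labels)
        assert pairwise_auc(s2.values, labels) == pytest.approx(
            pairwise_auc(s1.values, labels), abs=1e-9
        )

    def test_missing_feature_rejected(self, rng):
        cohort = cohort_from(rng.normal(size=(6, 1)),
                             ["good"] * 3 + ["poor"] * 3, [F1])
        model = fit_lda(cohort, [F1])
        with pytest.raises(InputError):
            discriminant_score(model, CohortTable(values=pd.DataFrame()))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12],
                      ["poor"] * 3 + ["good"] * 3, n_bootstrap=50, rng=0)
        assert res.auc == 1.0

    def test_null_labels_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "good", "poor")
        res = roc_auc(scores, labels, n_bootstrap=10, rng=1)
        assert abs(res.auc - 0.5) < 0.05

    def test_tie_example_matches_pairwise_oracle(self):
        scores = [1.0, 2.0, 2.0, 4.0]
        labels = ["poor", "poor", "good", "good"]
        res = roc_auc(scores, labels, n_bootstrap=50, rng=2)
        assert res.auc == brute_force_auc(scores, labels)

    def test_rank_auc_equals_pairwise_and_trapezoid_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            scores = rng.choice(np.arange(6, dtype=float), size=n)
            labels = np.where(rng.random(n) < 0.5, "good", "poor")
            if len(set(labels)) < 2:
                continue
            res = roc_auc(scores, labels, n_bootstrap=5, rng=3)
            expected = brute_force_auc(scores, labels)
            assert res.auc == pytest.approx(expected, abs=1e-12)
            trapezoid = np.trapezoid(res.curve[:, 1], res.curve[:, 0])
            assert trapezoid == pytest.approx(expected, abs=1e-12)

    def test_curve_endpoints_and_monotone(self, rng):
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.4, "good", "poor")
        res = roc_auc(scores, labels, n_bootstrap=10, rng=4)
        assert tuple(res.curve[0]) == (0.0, 0.0)
        assert tuple(res.curve[-1]) == (1.0, 1.0)
        assert (np.diff(res.curve[:, 0]) >= 0).all()
        assert (np.diff(res.curve[:, 1]) >= 0).all()

    def test_ci_brackets_auc(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 10), rng.normal(0, 1, 10)])
        labels = ["good"] * 10 + ["poor"] * 10
        res = roc_auc(scores, labels, n_bootstrap=500, rng=6)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, "good", "poor")
        res = roc_auc(scores, labels, n_bootstrap=5, rng=7)
        assert res.auc == pytest.approx(
            roc_auc_score((labels == "good").astype(int), scores)
        )

    def test_one_class_rejected(self):
        with pytest.raises(InputError):
            pairwise_auc(np.array([1.0, 2.0]), np.array(["good", "good"]))
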