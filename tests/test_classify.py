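"""ROC machinery, classifiers, and the derivation/validation protocol."""

import numpy as np
import pytest

import dcipred as dp
from dcipred.classify import hanley_se


def _fm(arr):
    arr = np.atleast_2d(np.asarray(arr, float))
    tags = [dict(kind="baseline", variable=f"c{j}", ds_minutes=None,
                 kernel_length=None, kernel_index=None)
            for j in range(arr.shape[1])]
    return dp.FeatureMatrix(arr, tags, [str(i) for i in range(arr.shape[0])])


class TestAuc:
    def test_perfectly_ordered(self):
        assert dp.auc(np.arange(6.0), np.array([0, 0, 0, 1, 1, 1])) == 1.0

    def test_all_scores_equal(self):
        assert dp.auc(np.ones(8), np.array([0, 1] * 4)) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        s = rng.normal(size=15)
        s[rng.choice(15, 4, replace=False)] = 0.5   # inject ties
        y = rng.integers(0, 2, 15)
        y[:2] = [0, 1]
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert dp.auc(s, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_complement_under_score_negation(self, rng):
        s = rng.normal(size=30)        # continuous, tie-free a.s.
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert dp.auc(s, y) + dp.auc(-s, y) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert dp.auc(np.exp(2 * s) + 1, y) == pytest.approx(dp.auc(s, y))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        assert dp.auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dp.auc(np.arange(4.0), np.zeros(4, int))


class TestHanleyCI:
    def test_degenerate_single_pair_se(self):
        # A=0.5, n_pos=n_neg=1: the formula collapses to sqrt(A(1-A))=0.5
        assert hanley_se(0.5, 1, 1) == pytest.approx(0.5)

    def test_perfect_auc_zero_width(self):
        lo, hi = dp.auc_ci_hanley(1.0, 10, 20)
        assert (lo, hi) == (1.0, 1.0)

    def test_matches_hand_evaluated_formula(self):
        a, n_pos, n_neg = 0.78, 30, 70
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        se = np.sqrt((a * (1 - a) + 29 * (q1 - a * a) + 69 * (q2 - a * a))
                     / (30 * 70))
        lo, hi = dp.auc_ci_hanley(a, n_pos, n_neg)
        assert lo == pytest.approx(a - 1.959963984540054 * se)
        assert hi == pytest.approx(a + 1.959963984540054 * se)

    def test_interval_clipped_to_unit(self):
        lo, hi = dp.auc_ci_hanley(0.98, 3, 3)
        assert 0.0 <= lo <= hi <= 1.0


class TestCompareAucCorrelated:
    def test_identical_scores(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        z, p = dp.compare_auc_correlated(s, s.copy(), y)
        assert z == 0.0 and p == 1.0

    def test_independent_scores_match_uncorrelated_test(self, rng):
        n = 400
        y = np.array([0, 1] * (n // 2))
        sa = rng.normal(size=n) + 0.8 * y
        sb = rng.normal(size=n) + 0.8 * y
        z, p = dp.compare_auc_correlated(sa, sb, y)
        a1, a2 = dp.auc(sa, y), dp.auc(sb, y)
        se1 = hanley_se(a1, n // 2, n // 2)
        se2 = hanley_se(a2, n // 2, n // 2)
        z_unc = (a1 - a2) / np.sqrt(se1 ** 2 + se2 ** 2)
        # empirical r is near 0, so z should be near the uncorrelated value
        assert z == pytest.approx(z_unc, abs=0.2 * abs(z_unc) + 0.05)

    def test_agrees_with_paired_bootstrap_in_direction_and_scale(self):
        rng = np.random.default_rng(5)
        n = 40
        y = np.array([0] * 25 + [1] * 15)
        latent = rng.normal(size=n)
        sa = latent + 1.0 * y + rng.normal(0, 0.6, n)
        sb = latent + 0.25 * y + rng.normal(0, 0.6, n)
        z, p = dp.compare_auc_correlated(sa, sb, y)
        # paired bootstrap over cases
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            diffs.append(dp.auc(sa[idx], y[idx]) - dp.auc(sb[idx], y[idx]))
        diffs = np.array(diffs)
        observed = dp.auc(sa, y) - dp.auc(sb, y)
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        p_boot = max(p_boot, 1 / len(diffs))
        assert np.sign(z) == np.sign(observed)
        assert p <= 2 * max(p_boot, 0.005) * 2 or p_boot <= 2 * p
        # loose two-sided factor-of-two agreement where both are informative
        if 0.005 < p_boot < 0.9:
            assert 0.5 * p_boot <= p <= 2.0 * p_boot or abs(p - p_boot) < 0.05

    def test_delong_flag(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        sb = s + rng.normal(0, 0.5, 50)
        z, p = dp.compare_auc_correlated(s, sb, y, method="delong")
        assert 0 <= p <= 1


class TestSplitCohort:
    def _cohort(self, n, n_pos, seed=0):
        recs = [dp.PatientRecord(id=str(i), dci=int(i < n_pos))
                for i in range(n)]
        return dp.Cohort(recs)

    def test_proportional_counts(self):
        cohort = self._cohort(100, 30)
        deriv, val = dp.split_cohort(cohort, 0.8, seed=4)
        assert len(deriv) == 80 and len(val) == 20
        assert deriv.labels().sum() == 24 and val.labels().sum() == 6

    def test_same_seed_reproduces_split(self):
        cohort = self._cohort(50, 20)
        a1, b1 = dp.split_cohort(cohort, 0.8, seed=9)
        a2, b2 = dp.split_cohort(cohort, 0.8, seed=9)
        assert a1.ids() == a2.ids() and b1.ids() == b2.ids()

    def test_disjoint_and_exhaustive(self):
        cohort = self._cohort(47, 13)
        a, b = dp.split_cohort(cohort, 0.8, seed=1)
        assert sorted(a.ids() + b.ids()) == sorted(cohort.ids())

    def test_prevalence_preserved_at_cohort_scale(self):
        cohort = self._cohort(488, 146)   # ~30% prevalence
        a, b = dp.split_cohort(cohort, 0.8, seed=3)
        diff = abs(a.labels().mean() - b.labels().mean())
        assert diff < 1 / 48

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            dp.split_cohort(self._cohort(10, 1), 0.8, seed=0)


class TestFit:
    def test_separable_toy_svm_reaches_training_auc_one(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 2)) - 2,
                       rng.normal(0, 0.3, (20, 2)) + 2])
        y = np.array([0] * 20 + [1] * 20)
        model = dp.fit(dp.ModelSpec("SVM-L"), _fm(X), y)
        assert dp.auc(model.score(_fm(X)), y) == 1.0

    def test_pls_full_rank_matches_ols(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        y[:4] = [0, 0, 1, 1]
        model = dp.fit(dp.ModelSpec("PLS", pls_components=4), _fm(X), y)
        scores = model.score(_fm(X))
        # OLS on the same standardized design
        Ft, _, _ = dp.impute_and_standardize(_fm(X))
        Z = np.column_stack([np.ones(30), Ft.values])
        beta, *_ = np.linalg.lstsq(Z, y.astype(float), rcond=None)
        np.testing.assert_allclose(scores, Z @ beta, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            dp.fit(dp.ModelSpec("PLS"), _fm(X), np.zeros(10, int))

    def test_duplicating_minority_matches_double_weight(self, rng):
        """Class weighting: duplicating every minority example is equivalent
        to weighting the class twice as much in the hinge loss."""
        from sklearn.svm import SVC
        X = np.vstack([rng.normal(0, 1.0, (16, 2)) - 1,
                       rng.normal(0, 1.0, (8, 2)) + 1])
        y = np.array([0] * 16 + [1] * 8)
        Xdup = np.vstack([X, X[y == 1]])
        ydup = np.concatenate([y, np.ones(8, int)])
        probe = rng.normal(size=(10, 2))
        m_w = SVC(kernel="linear", C=1.0, class_weight={0: 1.0, 1: 2.0},
                  tol=1e-10).fit(X, y)
        m_d = SVC(kernel="linear", C=1.0, tol=1e-10).fit(Xdup, ydup)
        np.testing.assert_allclose(m_w.decision_function(probe),
                                   m_d.decision_function(probe), atol=1e-6)

    def test_null_features_give_chance_auc(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 2, 200)
        y[:4] = [0, 0, 1, 1]
        res = dp.cv_median_auc(_fm(X), y, dp.ModelSpec("PLS"), runs=25, seed=0)
        assert 0.42 <= res.auc <= 0.58


class TestProtocol:
    def test_single_run_equals_manual_holdout(self, rng):
        X = rng.normal(size=(64, 3))
        y = (X[:, 0] + rng.normal(0, 1, 64) > 0).astype(int)
        spec = dp.ModelSpec("PLS")
        res = dp.cv_median_auc(_fm(X), y, spec, runs=1, holdout=0.25, seed=42)
        # manual reduction with the same seed stream
        from dcipred.classify import _stratified_split_idx
        rng2 = np.random.default_rng(42)
        hold, train = _stratified_split_idx(y, 0.25, rng2)
        model = dp.fit(spec, _fm(X).rows(train), y[train],
                       seed=int(rng2.integers(0, 2 ** 31)))
        expected = dp.auc(model.score(_fm(X).rows(hold)), y[hold])
        assert res.auc == pytest.approx(expected)

    def test_validation_result_has_wellformed_ci(self, rng):
        X = rng.normal(size=(80, 4))
        y = (X[:, 1] > 0).astype(int)
        res = dp.evaluate_validation(_fm(X[:60]), y[:60], _fm(X[60:]), y[60:],
                                     dp.ModelSpec("PLS"))
        assert res.ci_low <= res.auc <= res.ci_high

    def test_leakage_smoke_validation_equal_to_derivation(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        spec = dp.ModelSpec("PLS")
        res = dp.evaluate_validation(_fm(X), y, _fm(X), y, spec)
        model = dp.fit(spec, _fm(X), y)
        assert res.auc == pytest.approx(dp.auc(model.score(_fm(X)), y))

    def test_fitted_model_independent_of_validation_rows(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        spec = dp.ModelSpec("PLS", mrmr_k=2)
        probe = _fm(rng.normal(size=(5, 4)))
        m1 = dp.fit(spec, _fm(X), y, seed=0)
        m2 = dp.fit(spec, _fm(X), y, seed=0)
        np.testing.assert_array_equal(m1.score(probe), m2.score(probe))
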