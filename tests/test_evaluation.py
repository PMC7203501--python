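"""ROC/DeLong, PR-CV, DCA and univariate tests vs brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from pabifurc.evaluation import (
    chi2_2x2,
    dca_net_benefit,
    delong_paired_test,
    pr_curve_cv,
    recalibrate_scores,
    roc_auc_delong,
    ttest_groups,
)


def auc_pair_counting(scores, labels):
    """Exhaustive O(n^2) oracle: (concordant + ties/2) / (n+ * n-)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.arange(10, dtype=float)
        res = roc_auc_delong(scores, labels)
        assert res.auc == 1.0
        assert res.youden_sensitivity + res.youden_specificity - 1 == pytest.approx(1.0)

    def test_null_auc_near_half(self, rng):
        n = 2000
        scores = rng.standard_normal(n)
        labels = rng.integers(0, 2, size=n)
        res = roc_auc_delong(scores, labels)
        assert abs(res.auc - 0.5) < 3.0 * np.sqrt(res.variance)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 120))
            scores = rng.integers(0, 12, size=n).astype(float)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            res = roc_auc_delong(scores, labels)
            assert res.auc == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_delong([1.0, 2.0], [1, 1])

    def test_ci_within_unit_interval(self, rng):
        scores = rng.standard_normal(300)
        labels = (scores + rng.standard_normal(300) > 1.2).astype(int)
        res = roc_auc_delong(scores, labels)
        assert 0.0 <= res.ci95[0] <= res.auc <= res.ci95[1] <= 1.0

    def test_rank_invariance(self, rng):
        scores = rng.standard_normal(400)
        labels = (scores + rng.standard_normal(400) > 0.8).astype(int)
        a = roc_auc_delong(scores, labels)
        b = roc_auc_delong(np.exp(3.0 * scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, rel=1e-9)

    def test_youden_tie_breaks_to_higher_specificity(self):
        # two thresholds reach the same J: the higher cutoff must win
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 0, 1, 1])
        res = roc_auc_delong(scores, labels)
        assert res.youden_specificity == 1.0


class TestDelongPaired:
    def test_identical_scores(self, rng):
        scores = rng.standard_normal(200)
        labels = (scores > 0.5).astype(int)
        res = delong_paired_test(scores, scores, labels)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_monotone_transform_rank_invariance(self, rng):
        scores = rng.standard_normal(300)
        labels = (scores + rng.standard_normal(300) > 0.9).astype(int)
        res = delong_paired_test(scores, np.tanh(scores) * 7.0 + 2.0, labels)
        assert res.delta == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1.0, 2.0], [1.0], [0, 1])

    def test_variance_close_to_bootstrap(self, rng):
        """DeLong variance of the AUC difference within 15% of a
        2000-replicate bootstrap."""
        n = 500
        latent = rng.standard_normal(n)
        labels = (latent + rng.standard_normal(n) > 1.0).astype(int)
        scores_a = latent + 0.6 * rng.standard_normal(n)
        scores_b = 0.7 * latent + 0.9 * rng.standard_normal(n)
        res = delong_paired_test(scores_a, scores_b, labels)

        deltas = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            y = labels[idx]
            if y.sum() in (0, n):
                continue
            deltas.append(
                auc_pair_counting(scores_a[idx], y)
                - auc_pair_counting(scores_b[idx], y)
            )
        boot_var = np.var(deltas, ddof=1)
        assert res.variance == pytest.approx(boot_var, rel=0.15)

    def test_single_curve_variance_close_to_bootstrap(self, rng):
        n = 500
        latent = rng.standard_normal(n)
        labels = (latent + rng.standard_normal(n) > 1.0).astype(int)
        scores = latent + 0.5 * rng.standard_normal(n)
        res = roc_auc_delong(scores, labels)
        aucs = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            y = labels[idx]
            if y.sum() in (0, n):
                continue
            aucs.append(auc_pair_counting(scores[idx], y))
        assert res.variance == pytest.approx(np.var(aucs, ddof=1), rel=0.15)


class TestPrCurveCv:
    def test_perfect_scorer(self, rng):
        labels = rng.integers(0, 2, size=200)
        res = pr_curve_cv(labels.astype(float), labels, n_folds=10, seed=0)
        assert res.mean_precision == pytest.approx(1.0)

    def test_random_scorer_near_prevalence(self, rng):
        n = 2000
        prevalence = 0.115
        labels = (rng.uniform(size=n) < prevalence).astype(int)
        scores = rng.standard_normal(n)
        res = pr_curve_cv(scores, labels, n_folds=10, seed=1)
        se = np.std(res.fold_average_precision, ddof=1) / np.sqrt(res.n_folds_used)
        assert abs(res.mean_precision - labels.mean()) < max(3 * se, 0.05)

    def test_average_precision_matches_step_oracle(self, rng):
        """AP equals the brute-force sum over recall steps."""
        from sklearn.model_selection import StratifiedKFold

        n = 300
        x = rng.standard_normal(n)
        labels = (x + rng.standard_normal(n) > 1.0).astype(int)
        res = pr_curve_cv(x, labels, n_folds=5, seed=3)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        k = 0
        for _, te in skf.split(x.reshape(-1, 1), labels):
            y, s = labels[te], x[te]
            order = np.argsort(-s, kind="stable")
            y_sorted = y[order]
            tp = np.cumsum(y_sorted)
            precision = tp / np.arange(1, len(y_sorted) + 1)
            recall = tp / y_sorted.sum()
            drecall = np.diff(np.concatenate([[0.0], recall]))
            ap_oracle = float(np.sum(precision * drecall))
            assert res.fold_average_precision[k] == pytest.approx(ap_oracle, abs=1e-9)
            k += 1

    def test_empty_fold_skipped_with_warning(self):
        labels = np.array([1] * 3 + [0] * 97)
        scores = np.linspace(0, 1, 100)
        with pytest.warns(UserWarning, match="no events"):
            res = pr_curve_cv(scores, labels, n_folds=10, seed=0)
        assert res.n_folds_skipped > 0
        assert res.n_folds_used + res.n_folds_skipped == 10


class TestDca:
    def test_perfect_predictor(self):
        labels = np.array([1] * 20 + [0] * 80)
        prob = labels.astype(float)
        res = dca_net_benefit(prob, labels, [0.1])
        assert res.net_benefit_model[0] == pytest.approx(0.2)

    def test_treat_all_zero_at_prevalence_threshold(self, rng):
        labels = (rng.uniform(size=1000) < 0.2).astype(int)
        prevalence = labels.mean()
        res = dca_net_benefit(labels.astype(float), labels, [prevalence])
        assert res.net_benefit_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_confusion_matrix_oracle(self, rng):
        n = 400
        prob = rng.uniform(size=n)
        labels = (rng.uniform(size=n) < prob).astype(int)
        thresholds = np.linspace(0.05, 0.95, 11)
        res = dca_net_benefit(prob, labels, thresholds)
        for i, pt in enumerate(thresholds):
            treat = prob >= pt
            tp = np.sum(treat & (labels == 1))
            fp = np.sum(treat & (labels == 0))
            expected = tp / n - (fp / n) * pt / (1 - pt)
            assert res.net_benefit_model[i] == pytest.approx(expected, abs=1e-12)

    def test_model_never_exceeds_prevalence(self, rng):
        n = 500
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        prob = np.clip(rng.uniform(size=n), 0.01, 0.99)
        res = dca_net_benefit(prob, labels, np.linspace(0.05, 0.95, 19))
        assert np.all(res.net_benefit_model <= labels.mean() + 1e-12)
        assert np.all(res.net_benefit_none == 0.0)

    def test_threshold_bounds_rejected(self):
        with pytest.raises(ValueError):
            dca_net_benefit([0.5], [1], [0.0])
        with pytest.raises(ValueError):
            dca_net_benefit([0.5], [1], [1.0])

    def test_recalibration_monotone_and_bounded(self, rng):
        scores = rng.standard_normal(300)
        labels = (scores + rng.standard_normal(300) > 0.5).astype(int)
        prob = recalibrate_scores(scores, labels)
        assert np.all((prob > 0) & (prob < 1))
        order = np.argsort(scores)
        assert np.all(np.diff(prob[order]) >= -1e-12)


class TestTTest:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = ttest_groups(x, x.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_permutation_oracle(self, rng):
        a = rng.standard_normal(30) + 0.8
        b = rng.standard_normal(35)
        t_obs, p = ttest_groups(a, b, equal_var=True)
        pooled = np.concatenate([a, b])
        n_perm = 10000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm, _ = stats.ttest_ind(perm[: len(a)], perm[len(a) :])
            if abs(t_perm) >= abs(t_obs):
                count += 1
        p_perm = count / n_perm
        mc_se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(p - p_perm) < max(4 * mc_se, 0.004)

    def test_summary_path_equals_raw(self, rng):
        a = rng.standard_normal(40) + 0.3
        b = rng.standard_normal(50)
        t_raw, p_raw = ttest_groups(a, b, equal_var=True)
        t_sum, p_sum = ttest_groups(
            stats_a=(len(a), a.mean(), a.std(ddof=1)),
            stats_b=(len(b), b.mean(), b.std(ddof=1)),
            equal_var=True,
        )
        assert t_sum == pytest.approx(t_raw, abs=1e-12)
        assert p_sum == pytest.approx(p_raw, abs=1e-12)

    def test_welch_variant_differs_under_heteroscedasticity(self, rng):
        a = 5.0 * rng.standard_normal(20)
        b = rng.standard_normal(80)
        t_pooled, _ = ttest_groups(a, b, equal_var=True)
        t_welch, _ = ttest_groups(a, b, equal_var=False)
        assert t_pooled != t_welch

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_groups([1.0, 1.0], [2.0, 2.0])

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ttest_groups([1.0], [2.0, 3.0])


class TestChi2:
    def test_published_dilation_table(self):
        """Expected-count hand computation for the [[13,21],[31,231]]
        dilation table; the printed bound is p < 0.001."""
        table = np.array([[13, 21], [31, 231]])
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        oracle = float(((table - expected) ** 2 / expected).sum())
        stat, p = chi2_2x2(table)
        assert stat == pytest.approx(oracle, abs=1e-12)
        assert stat == pytest.approx(16.6, abs=0.1)
        assert p < 0.001

    def test_proportional_table_zero(self):
        stat, p = chi2_2x2([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[0, 0], [5, 7]])

    def test_yates_correction_switchable(self):
        stat_plain, _ = chi2_2x2([[13, 21], [31, 231]], correction=False)
        stat_yates, _ = chi2_2x2([[13, 21], [31, 231]], correction=True)
        assert stat_yates < stat_plain

    def test_null_distribution_matches_chi2(self, rng):
        """Multinomial simulation under independence (n=60): the
        empirical exceedance of the 0.05 critical value matches the
        chi-square tail within Monte-Carlo + discreteness slack."""
        p_row, p_col = 0.4, 0.5
        probs = np.array(
            [p_row * p_col, p_row * (1 - p_col),
             (1 - p_row) * p_col, (1 - p_row) * (1 - p_col)]
        )
        draws = rng.multinomial(60, probs, size=100000).reshape(-1, 2, 2)
        ok = (draws.sum(axis=2) > 0).all(axis=1) & (draws.sum(axis=1) > 0).all(axis=1)
        draws = draws[ok].astype(float)
        rows = draws.sum(axis=2, keepdims=True)
        cols = draws.sum(axis=1, keepdims=True)
        n = draws.sum(axis=(1, 2), keepdims=True)
        expected = rows * cols / n
        stat = ((draws - expected) ** 2 / expected).sum(axis=(1, 2))
        crit = stats.chi2.ppf(0.95, df=1)
        frac = (stat > crit).mean()
        assert frac == pytest.approx(0.05, abs=0.01)
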