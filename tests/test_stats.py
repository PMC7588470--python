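"""Group comparison, ROC/AUC and Youden cut-off statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import strainrisk as sr


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, independent arithmetic path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Max J over every candidate threshold with the rule score >= cutoff."""
    scores, labels = np.asarray(scores), np.asarray(labels, bool)
    best = -np.inf
    for thr in np.r_[np.unique(scores), np.inf]:
        pred = scores >= thr
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec - 1)
    return best


class TestStudentT:
    def test_identical_groups(self):
        t, p = sr.student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_clear_separation(self):
        # with df = 4 the attainable floor for a 10-unit shift is ~2.6e-4
        _, p = sr.student_t_test([1, 2, 3], [11, 12, 13])
        assert p < 1e-3
        _, p_large = sr.student_t_test(list(range(12)),
                                       [x + 10 for x in range(12)])
        assert p_large < 1e-6

    def test_matches_textbook_formula(self):
        a, b = [0.1, 0.2, 0.3], [0.2, 0.3, 0.5]
        t, p = sr.student_t_test(a, b)
        t_ref, p_ref = pooled_t_oracle(a, b)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_degenerate_zero_variance(self):
        assert sr.student_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = sr.student_t_test([3.0, 3.0], [2.0, 2.0])
        assert t == np.inf and p == 0.0

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.normal(0.0, 0.1, 8)
        b = rng.normal(0.3, 2.0, 30)
        _, p_student = sr.student_t_test(a, b, equal_var=True)
        _, p_welch = sr.student_t_test(a, b, equal_var=False)
        assert p_student != p_welch

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sr.student_t_test([1.0], [1.0, 2.0])


class TestRocAuc:
    def test_perfect_separation(self):
        roc = sr.roc_and_auc([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        assert roc.points[0].tolist() == [0.0, 0.0]
        assert roc.points[-1].tolist() == [1.0, 1.0]

    def test_tie_gets_half_credit(self):
        roc = sr.roc_and_auc([0.2, 0.2], [1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sr.roc_and_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_on_small_cohorts(self, rng):
        for _ in range(300):
            n_pos = rng.integers(1, 5)
            n_neg = rng.integers(1, 5)
            # coarse rounding forces plenty of ties
            scores = np.round(rng.uniform(0, 1, n_pos + n_neg), 1)
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            roc = sr.roc_and_auc(scores, labels)
            assert roc.auc == pytest.approx(pair_count_auc(scores, labels),
                                            abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            scores = rng.uniform(0, 1, 40)
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            roc = sr.roc_and_auc(scores, labels)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores),
                                            abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        roc = sr.roc_and_auc(scores, labels)
        roc2 = sr.roc_and_auc(np.exp(3 * scores), labels)
        assert roc2.auc == pytest.approx(roc.auc, abs=1e-12)
        j1 = sr.youden_cutoff(roc).youden_j
        j2 = sr.youden_cutoff(roc2).youden_j
        assert j1 == pytest.approx(j2, abs=1e-12)


class TestYouden:
    def test_perfectly_separated_cutoff_is_observed_value(self):
        roc = sr.roc_and_auc([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1])
        res = sr.youden_cutoff(roc)
        assert res.cutoff == pytest.approx(0.3)
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.youden_j == pytest.approx(1.0)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(300):
            n_pos = rng.integers(1, 4)
            n_neg = rng.integers(1, 4)
            scores = np.round(rng.uniform(0, 1, n_pos + n_neg), 1)
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            res = sr.youden_cutoff(sr.roc_and_auc(scores, labels))
            assert res.youden_j == pytest.approx(
                exhaustive_youden(scores, labels), abs=1e-12)

    def test_tie_break_prefers_higher_specificity(self):
        # cutoffs 0.2 and 0.4 both reach J = 0.5; the larger must win
        scores = [0.1, 0.3, 0.2, 0.4]
        labels = [0, 0, 1, 1]
        res = sr.youden_cutoff(sr.roc_and_auc(scores, labels))
        assert res.cutoff == pytest.approx(0.4)

    def test_reported_operating_point_identities(self):
        m = sr.confusion_metrics(tp=15, fn=9, tn=24, fp=3)
        assert m["sensitivity"] == pytest.approx(62.5)
        assert m["specificity"] == pytest.approx(100 * 24 / 27)
        assert m["youden_j"] == pytest.approx(0.625 + 24 / 27 - 1)


class TestConditionSummary:
    def test_summary_shape_and_degenerate_sd(self):
        grid_u = sr.StrainGrid(np.full((4, 4), 0.10))
        grid_r = sr.StrainGrid(np.full((4, 4), 0.20))
        records = [
            sr.AneurysmRecord("U01", False, 0.10, grid_u),
            sr.AneurysmRecord("U02", False, 0.10, grid_u),
            sr.AneurysmRecord("R01", True, 0.20, grid_r),
            sr.AneurysmRecord("R02", True, 0.20, grid_r),
        ]
        df = sr.condition_summary(records)
        assert len(df) == 16
        assert (df["sd_unruptured"] == 0).all()
        assert (df["p_value"] == 0).all()  # zero variance, separated means

    def test_small_group_rejected(self):
        grid = sr.StrainGrid(np.full((4, 4), 0.1))
        records = [sr.AneurysmRecord("U01", False, 0.1, grid),
                   sr.AneurysmRecord("R01", True, 0.1, grid),
                   sr.AneurysmRecord("R02", True, 0.1, grid)]
        with pytest.raises(ValueError):
            sr.condition_summary(records)

    def test_membrane_mode_noiseless_conservation(self):
        spec = sr.CohortSpec(condition_noise_cv=0.0,
                             unruptured_amplification="membrane",
                             ruptured_amplification="membrane", seed=9)
        df = sr.condition_summary(sr.generate_cohort(spec))
        for col in ("mean_unruptured", "mean_ruptured"):
            prod = (df[col] * df["thickness_fraction"]
                    * df["modulus_fraction"])
            assert np.allclose(prod, prod.iloc[0], rtol=1e-12)

    def test_groups_significantly_separated_at_defaults(self):
        df = sr.condition_summary(sr.generate_cohort(sr.CohortSpec(seed=4)))
        assert (df["mean_ruptured"] > df["mean_unruptured"]).all()
        assert (df["p_value"] < 0.05).sum() >= 14


class TestAnalyticAuc:
    def test_simulated_baseline_auc_converges_to_closed_form(self, rng):
        target = sr.analytic_baseline_auc(0.053, 0.026, 0.094, 0.048)
        assert target == pytest.approx(0.80, abs=0.01)
        neg = sr.sample_lognormal(0.053, 0.026, 4000, rng)
        pos = sr.sample_lognormal(0.094, 0.048, 4000, rng)
        roc = sr.roc_and_auc(np.r_[neg, pos],
                             np.r_[np.zeros(4000), np.ones(4000)])
        assert roc.auc == pytest.approx(target, abs=0.02)
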