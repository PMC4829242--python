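"""Statistical toolkit, each operation against an independent oracle."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import conjscreen.diagnostics as dx
from conjscreen.errors import (
    DegenerateVarianceError,
    SampleSizeError,
    UndefinedStatisticError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# contingency + summary

class TestContingency:
    def test_perfect_prediction(self):
        truth = [1] * 5 + [0] * 3
        t = dx.build_contingency(truth, truth)
        assert (t.tp, t.tn, t.fp, t.fn) == (5, 3, 0, 0)

    def test_all_positive_prediction(self):
        t = dx.build_contingency([1] * 10, [1] * 3 + [0] * 7)
        assert (t.tp, t.fp) == (3, 7)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            dx.build_contingency([], [])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            dx.build_contingency([1], [1, 0])


class TestDiagnosticSummary:
    def test_internal_consistency(self):
        s = dx.diagnostic_summary(dx.ContingencyTable(tp=13, fn=10, fp=4, tn=20))
        t = s.table
        assert s.accuracy == pytest.approx((t.tp + t.tn) / t.total)
        assert s.positive_lr == pytest.approx(s.sensitivity / (1 - s.specificity))
        for est, ci in [
            (s.sensitivity, s.sensitivity_ci),
            (s.specificity, s.specificity_ci),
            (s.ppv, s.ppv_ci),
            (s.npv, s.npv_ci),
            (s.accuracy, s.accuracy_ci),
        ]:
            assert ci[0] <= est <= ci[1]

    def test_perfect_table(self):
        s = dx.diagnostic_summary(dx.ContingencyTable(tp=5, fn=0, fp=0, tn=5))
        assert s.sensitivity == s.specificity == s.ppv == s.npv == s.accuracy == 1.0
        assert s.positive_lr == np.inf

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            dx.diagnostic_summary(dx.ContingencyTable(tp=3, fn=2, fp=0, tn=0))

    def test_clopper_pearson_matches_beta_closed_form(self):
        for k, n in [(14, 15), (3, 10), (0, 8), (8, 8)]:
            lo, hi = dx.proportion_ci(k, n)
            exp_lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
            exp_hi = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
            assert lo == pytest.approx(exp_lo) and hi == pytest.approx(exp_hi)


# ---------------------------------------------------------------------------
# Fisher exact

def fisher_enumeration(t: dx.ContingencyTable) -> float:
    """Oracle: sum hypergeometric probabilities of all tables (at fixed
    margins) no more probable than the observed one."""
    r1, r2, c1 = t.tp + t.fn, t.fp + t.tn, t.tp + t.fp
    n = r1 + r2

    def pr(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = pr(t.tp)
    return sum(
        pr(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pr(k) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_diagonal_table(self):
        p = dx.fisher_exact(dx.ContingencyTable(tp=5, fn=0, fp=0, tn=5))
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_independent_table(self):
        assert dx.fisher_exact(dx.ContingencyTable(tp=2, fn=2, fp=2, tn=2)) == 1.0

    @given(
        tp=st.integers(0, 15), fn=st.integers(0, 15),
        fp=st.integers(0, 15), tn=st.integers(0, 15),
    )
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_matches_enumeration(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        t = dx.ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)
        assert dx.fisher_exact(t) == pytest.approx(fisher_enumeration(t), abs=1e-9)


# ---------------------------------------------------------------------------
# ROC / AUC / Youden

def auc_bruteforce(scores, labels):
    """Oracle: Mann-Whitney probability that an anaemic score is below a
    non-anaemic score, ties counted 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum((p < q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def youden_bruteforce(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    distinct = np.unique(s)
    cands = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
    best_t, best_j = None, -np.inf
    for t in cands:
        pred = s < t
        j = pred[y].mean() + (1 - pred[~y].mean())
        if j > best_j:  # strict: keeps the lowest threshold on ties
            best_j, best_t = j, t
    return best_t, best_j


class TestROC:
    def test_perfect_separation(self):
        c = dx.roc_curve([10, 12, 20, 25], [1, 1, 0, 0])
        assert c.auc == 1.0
        best = dx.youden_threshold(c)
        assert best.sensitivity == best.specificity == 1.0
        assert best.threshold == 16.0

    def test_symmetric_ties(self):
        assert dx.roc_curve([10, 20, 10, 20], [1, 1, 0, 0]).auc == 0.5

    def test_worked_example(self):
        c = dx.roc_curve([10, 18, 15, 22, 30], [1, 1, 0, 0, 0])
        assert c.auc == pytest.approx(5 / 6)
        best = dx.youden_threshold(c)
        assert best.threshold == 20.0
        assert best.sensitivity == 1.0
        assert best.specificity == pytest.approx(2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            dx.roc_curve([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(1, 13, size=2)
        scores = np.concatenate(
            [rng.integers(0, 15, n_pos), rng.integers(0, 15, n_neg)]
        ).astype(float)
        labels = np.array([True] * n_pos + [False] * n_neg)
        c = dx.roc_curve(scores, labels)
        assert c.auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_youden_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 21))
        scores = rng.normal(size=n).round(1)
        labels = np.zeros(n, bool)
        labels[: n // 2] = True
        if labels.all() or not labels.any():
            return
        c = dx.roc_curve(scores, labels)
        best = dx.youden_threshold(c)
        t_exp, j_exp = youden_bruteforce(scores, labels)
        assert best.threshold == pytest.approx(t_exp)
        assert best.sensitivity + best.specificity == pytest.approx(j_exp)

    def test_anti_diagnostic_scores(self):
        # higher scores in the anaemic class: no cut-off beats chance
        c = dx.roc_curve([5.0, 6.0, 1.0, 2.0], [1, 1, 0, 0])
        best = dx.youden_threshold(c)
        assert best.sensitivity + best.specificity <= 1.0 + 1e-9

    def test_monotone_sweep(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.5
        labels[0], labels[1] = True, False
        c = dx.roc_curve(scores, labels)
        sens = [p[1] for p in c.points]
        fpr = [p[2] for p in c.points]
        assert np.all(np.diff(sens) >= 0) and np.all(np.diff(fpr) >= 0)


class TestAucCI:
    def test_truncation(self):
        lo, hi = dx.auc_ci(1.0, 5, 5)
        assert hi == 1.0
        lo, hi = dx.auc_ci(0.5, 1, 1)
        assert lo == 0.0 and hi == 1.0

    def test_hanley_mcneil_closed_form(self):
        a, n1, n2 = 0.8, 15, 32
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n2 - 1) * (q2 - a**2)) / (n1 * n2)
        )
        lo, hi = dx.auc_ci(a, n1, n2)
        assert lo == pytest.approx(a - 1.959964 * se, abs=1e-5)
        assert hi == pytest.approx(a + 1.959964 * se, abs=1e-5)


# ---------------------------------------------------------------------------
# regression

class TestLinearFit:
    def test_exact_line(self):
        fit = dx.linear_fit([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_ols(self):
        fit = dx.linear_fit([0, 1, 2], [0, 2, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1 / 3)
        assert fit.r_squared == pytest.approx(0.75)

    def test_n2_rejected(self):
        with pytest.raises(ValidationError):
            dx.linear_fit([0, 1], [0, 1])

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            dx.linear_fit([1, 1, 1], [0, 1, 2])

    def test_residuals_orthogonal_to_x(self, rng):
        x = rng.uniform(60, 160, 40)
        y = 0.1 * x + rng.normal(0, 2, 40)
        fit = dx.linear_fit(x, y)
        resid = y - fit.intercept - fit.slope * x
        assert np.sum(x * resid) == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# kappa, CV

class TestKappa:
    def test_perfect_agreement(self):
        r = [0, 0, 1, 1, 0, 1]
        assert dx.cohens_kappa(r, r).kappa == pytest.approx(1.0)

    def test_hand_example(self):
        # agreement table [[4,1],[1,4]]: po=0.8, pe=0.5 -> kappa=0.6
        r1 = [0] * 5 + [1] * 5
        r2 = [0] * 4 + [1] + [0] + [1] * 4
        assert dx.cohens_kappa(r1, r2).kappa == pytest.approx(0.6)

    def test_chance_level(self):
        # independent with po exactly equal to pe
        r1 = [0, 0, 1, 1]
        r2 = [0, 1, 0, 1]
        assert dx.cohens_kappa(r1, r2).kappa == pytest.approx(0.0)

    def test_both_constant_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dx.cohens_kappa([1, 1, 1], [1, 1, 1])

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=30))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetric_and_rename_invariant(self, pairs):
        r1 = [a for a, _ in pairs]
        r2 = [b for _, b in pairs]
        try:
            k12 = dx.cohens_kappa(r1, r2).kappa
        except UndefinedStatisticError:
            return
        assert dx.cohens_kappa(r2, r1).kappa == pytest.approx(k12)
        renamed1 = ["x" if v else "y" for v in r1]
        renamed2 = ["x" if v else "y" for v in r2]
        assert dx.cohens_kappa(renamed1, renamed2).kappa == pytest.approx(k12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        r1 = rng.integers(0, 2, 50)
        r2 = np.where(rng.random(50) < 0.8, r1, 1 - r1)
        assert dx.cohens_kappa(r1, r2).kappa == pytest.approx(
            cohen_kappa_score(r1, r2)
        )


class TestCV:
    def test_hand_example(self):
        res = dx.coefficient_of_variation([98, 100, 102])
        assert res.sd == pytest.approx(2.0)
        assert res.cv_percent == pytest.approx(2.0)

    def test_constant_values(self):
        assert dx.coefficient_of_variation([7, 7, 7]).cv_percent == 0.0

    def test_n1_rejected(self):
        with pytest.raises(SampleSizeError):
            dx.coefficient_of_variation([5])

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dx.coefficient_of_variation([-1, 1])


# ---------------------------------------------------------------------------
# ANOVA, paired t, normality

def twoway_oracle(values, fa, fb):
    """Textbook balanced two-way ANOVA (main effects) sums of squares."""
    values = np.asarray(values, float)
    fa, fb = np.asarray(fa), np.asarray(fb)
    grand = values.mean()
    ss_a = sum(
        (values[fa == a]).size * (values[fa == a].mean() - grand) ** 2
        for a in np.unique(fa)
    )
    ss_b = sum(
        (values[fb == b]).size * (values[fb == b].mean() - grand) ** 2
        for b in np.unique(fb)
    )
    ss_tot = ((values - grand) ** 2).sum()
    ss_res = ss_tot - ss_a - ss_b
    df_a, df_b = len(np.unique(fa)) - 1, len(np.unique(fb)) - 1
    df_res = values.size - 1 - df_a - df_b
    return (ss_a / df_a) / (ss_res / df_res), (ss_b / df_b) / (ss_res / df_res)


class TestTwoWayAnova:
    def make_design(self, rng):
        subs, lights, vals = [], [], []
        effects_s = {0: 0.0, 1: 1.5, 2: -1.0}
        effects_l = {"a": 0.0, "b": 2.0, "c": -0.5}
        for s in range(3):
            for li in "abc":
                for _ in range(5):
                    subs.append(f"S{s}")
                    lights.append(li)
                    vals.append(20 + effects_s[s] + effects_l[li] + rng.normal(0, 0.5))
        return np.array(vals), np.array(lights), np.array(subs)

    def test_matches_textbook_oracle(self, rng):
        vals, lights, subs = self.make_design(rng)
        res = dx.two_way_anova(vals, lights, subs)
        f_l, f_s = twoway_oracle(vals, lights, subs)
        assert res.effects["lighting"].F == pytest.approx(f_l)
        assert res.effects["subject"].F == pytest.approx(f_s)

    def test_all_equal_values(self):
        res = dx.two_way_anova([5.0] * 8, list("aabbaabb"), list("xxxxyyyy"))
        assert res.effects["lighting"].F == 0.0
        assert res.effects["subject"].F == 0.0

    def test_pure_factor_effect(self):
        # lighting fully explains the data; subject has no effect
        res = dx.two_way_anova(
            [10, 10, 20, 20], ["a", "a", "b", "b"], ["x", "y", "x", "y"]
        )
        assert res.effects["lighting"].F == np.inf
        assert res.effects["subject"].F == 0.0

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            dx.two_way_anova([1.0, 2.0], ["a", "a"], ["x", "y"])


class TestOneWayAnova:
    def test_identical_groups(self):
        res = dx.one_way_anova_bonferroni([[1.0, 2.0], [1.0, 2.0]])
        assert res.effects["group"].F == 0.0
        assert res.pairwise[0].p_adjusted == 1.0

    def test_hand_f_and_pairwise(self, rng):
        g1 = rng.normal(10, 1, 6)
        g2 = rng.normal(12, 1, 5)
        g3 = rng.normal(15, 1, 7)
        res = dx.one_way_anova_bonferroni({"a": g1, "b": g2, "c": g3})
        f_scipy, p_scipy = stats.f_oneway(g1, g2, g3)
        assert res.effects["group"].F == pytest.approx(f_scipy)
        assert res.effects["group"].p == pytest.approx(p_scipy)
        # Bonferroni: adjusted = min(1, 3 * raw)
        for c in res.pairwise:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))

    def test_zero_residual_guard(self):
        res = dx.one_way_anova_bonferroni([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0]])
        assert res.effects["group"].F == np.inf
        equal = [c for c in res.pairwise if c.difference == 0]
        assert len(equal) == 1 and equal[0].p_adjusted == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            dx.one_way_anova_bonferroni([[1.0], [2.0, 3.0]])


class TestPairedT:
    def test_hand_example(self):
        t, p = dx.paired_t([2, 3, 5], [1, 2, 3])
        assert t == pytest.approx(4.0)
        assert p == pytest.approx(2 * stats.t.sf(4.0, 2))

    def test_identical_pairs_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            dx.paired_t([1, 2, 3], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            dx.paired_t([1, 2], [1, 2, 3])

    def test_matches_scipy(self, rng):
        a = rng.normal(20, 2, 15)
        b = a - rng.normal(1, 0.5, 15)
        t, p = dx.paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(1)
        _, p = dx.normality_test(rng.normal(size=500))
        assert p > 0.05

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(1)
        _, p = dx.normality_test(rng.exponential(size=500))
        assert p < 0.001

    def test_small_n_rejected(self):
        with pytest.raises(SampleSizeError):
            dx.normality_test([1.0, 2.0, 3.0, 4.0, 5.0])
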