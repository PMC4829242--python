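"""Diagnostic-test and study statistics.

Covers the complete statistical toolkit of the screening analysis:
2x2 contingency evaluation with exact (Clopper-Pearson) confidence
intervals, Fisher's exact test, ROC curves with Youden-index threshold
selection, ordinary least-squares regression, Cohen's kappa, coefficient
of variation, one- and two-way ANOVA, the paired t test and the
D'Agostino-Pearson omnibus normality test.

Conventions fixed across the module: the positive class is "anaemic";
a score (mean palpebral EI) predicts anaemia when it is *strictly
below* the cut-off; all p values are two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import (
    DegenerateVarianceError,
    SampleSizeError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "ContingencyTable",
    "DiagnosticSummary",
    "ROCCurve",
    "ThresholdResult",
    "RegressionFit",
    "KappaResult",
    "AnovaResult",
    "CVResult",
    "build_contingency",
    "proportion_ci",
    "diagnostic_summary",
    "fisher_exact",
    "roc_curve",
    "auc_ci",
    "youden_threshold",
    "linear_fit",
    "cohens_kappa",
    "coefficient_of_variation",
    "two_way_anova",
    "one_way_anova_bonferroni",
    "paired_t",
    "normality_test",
]


# ---------------------------------------------------------------------------
# Contingency tables and diagnostic summaries

@dataclass
class ContingencyTable:
    """Predicted-anaemic x truly-anaemic counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.total < 1:
            raise ValidationError("contingency table must contain observations")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_matrix(self) -> np.ndarray:
        """Rows = truth (anaemic first), columns = prediction."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def build_contingency(predictions, truths) -> ContingencyTable:
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    if pred.size == 0:
        raise ValidationError("empty label sequences")
    if pred.shape != truth.shape:
        raise ValidationError("predictions and truths must have equal length")
    return ContingencyTable(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided Clopper-Pearson interval for ``k`` successes of
    ``n``, from beta-distribution quantiles."""
    if not 0 <= k <= n or n < 1:
        raise ValidationError("need 0 <= k <= n with n >= 1")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class DiagnosticSummary:
    """Point estimates with exact CIs for one classifier/rater."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    positive_lr: float
    fisher_p: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    ci_level: float
    table: ContingencyTable


def diagnostic_summary(
    table: ContingencyTable, ci_level: float = 0.95
) -> DiagnosticSummary:
    t = table
    if t.tp + t.fn < 1 or t.fp + t.tn < 1:
        raise ValidationError("both truth classes must be represented")
    sens = t.tp / (t.tp + t.fn)
    spec = t.tn / (t.fp + t.tn)
    ppv = t.tp / (t.tp + t.fp) if t.tp + t.fp else float("nan")
    npv = t.tn / (t.tn + t.fn) if t.tn + t.fn else float("nan")
    acc = (t.tp + t.tn) / t.total
    lr = sens / (1.0 - spec) if spec < 1.0 else float("inf")

    def ci(k, n):
        return proportion_ci(k, n, ci_level) if n else (float("nan"), float("nan"))

    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        positive_lr=lr,
        fisher_p=fisher_exact(t),
        sensitivity_ci=ci(t.tp, t.tp + t.fn),
        specificity_ci=ci(t.tn, t.fp + t.tn),
        ppv_ci=ci(t.tp, t.tp + t.fp),
        npv_ci=ci(t.tn, t.tn + t.fn),
        accuracy_ci=ci(t.tp + t.tn, t.total),
        ci_level=ci_level,
        table=t,
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of
    all tables (at fixed margins) no more likely than the observed."""
    p = stats.fisher_exact(table.as_matrix(), alternative="two-sided")[1]
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# ROC analysis

@dataclass
class ROCCurve:
    """ROC sweep for scores where *lower* predicts the positive class.

    ``points`` is a list of ``(threshold, sensitivity, fpr)`` triples at
    candidate cut-offs: midpoints between consecutive distinct scores
    plus -inf/+inf sentinels. Prediction rule: positive iff
    ``score < threshold``.
    """

    points: list[tuple[float, float, float]]
    auc: float
    n_pos: int
    n_neg: int
    orientation: str = "lower score predicts positive"

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])


def roc_curve(scores, labels) -> ROCCurve:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    points = []
    for t in thresholds:
        pred = s < t
        sens = float(pred[y].mean())
        fpr = float(pred[~y].mean())
        points.append((float(t), sens, fpr))
    fprs = np.array([p[2] for p in points])
    senss = np.array([p[1] for p in points])
    auc = float(np.trapezoid(senss, fprs))
    return ROCCurve(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg)


def auc_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil standard-error interval for an AUC, truncated to
    [0, 1]. Approximate; intended for reporting, not inference."""
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("need at least one observation per class")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return max(0.0, a - z * se), min(1.0, a + z * se)


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float


def youden_threshold(curve: ROCCurve) -> ThresholdResult:
    """Cut-off maximising sensitivity + specificity; ties broken toward
    the lower threshold (higher specificity)."""
    sums = np.array([sens + (1.0 - fpr) for _, sens, fpr in curve.points])
    best = int(np.argmax(sums))  # argmax takes the first = lowest threshold
    t, sens, fpr = curve.points[best]
    return ThresholdResult(threshold=t, sensitivity=sens, specificity=1.0 - fpr)


# ---------------------------------------------------------------------------
# Regression

@dataclass
class RegressionFit:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    p_zero_slope: float
    n: int


def linear_fit(x, y) -> RegressionFit:
    """OLS of ``y`` (EI) on ``x`` (haemoglobin, g/L)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValidationError("need n >= 3 for a regression with a slope test")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope is unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        r_squared=float(model.rsquared),
        p_zero_slope=float(model.pvalues[1]),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Agreement and variability

@dataclass
class KappaResult:
    kappa: float
    p_value: float
    n: int


def cohens_kappa(r1, r2) -> KappaResult:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement from marginal
    products; the p value is the large-sample z test of kappa = 0 using
    the null standard error.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length rating vectors, n >= 2")
    labels = sorted(set(a.tolist()) | set(b.tolist()), key=repr)
    k = len(labels)
    n = a.size
    idx = {lab: i for i, lab in enumerate(labels)}
    conf = np.zeros((k, k))
    for ai, bi in zip(a, b):
        conf[idx[ai], idx[bi]] += 1
    conf /= n
    po = float(np.trace(conf))
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0:
        raise UndefinedStatisticError(
            "chance agreement is 1; kappa is undefined (both raters constant)"
        )
    kappa = (po - pe) / (1.0 - pe)
    # null SE of kappa (Fleiss/Cohen large-sample form under kappa = 0)
    se0 = np.sqrt(
        (pe + pe**2 - float(np.sum(row * col * (row + col)))) / n
    ) / (1.0 - pe)
    if se0 == 0:
        p = 0.0 if kappa != 0 else 1.0
    else:
        z = kappa / se0
        p = float(2.0 * stats.norm.sf(abs(z)))
    return KappaResult(kappa=float(kappa), p_value=p, n=n)


@dataclass
class CVResult:
    mean: float
    sd: float
    cv_percent: float
    n: int


def coefficient_of_variation(values) -> CVResult:
    """100 x sample SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise SampleSizeError("coefficient of variation needs n >= 2")
    mean = float(v.mean())
    if mean == 0:
        raise UndefinedStatisticError("CV is undefined for zero-mean data")
    sd = float(v.std(ddof=1))
    return CVResult(mean=mean, sd=sd, cv_percent=100.0 * sd / abs(mean), n=v.size)


# ---------------------------------------------------------------------------
# ANOVA and t tests

@dataclass
class FactorEffect:
    name: str
    F: float
    df: float
    p: float


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    difference: float
    t: float
    p_raw: float
    p_adjusted: float


@dataclass
class AnovaResult:
    effects: dict[str, FactorEffect]
    residual_df: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def _guarded_f(effect_ss, effect_df, resid_ss, resid_df):
    """F with a zero-residual guard: a perfectly explained design gives
    an infinite F for any non-zero effect and 0 for a null effect."""
    if resid_df <= 0 or resid_ss <= 1e-12 * max(effect_ss, 1.0):
        if effect_ss <= 1e-12:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (effect_ss / effect_df) / (resid_ss / resid_df)
    p = float(stats.f.sf(f, effect_df, resid_df))
    return float(f), p


def two_way_anova(
    values, factor_a, factor_b, names: tuple[str, str] = ("lighting", "subject"),
    interaction: bool = False,
) -> AnovaResult:
    """Two-way ANOVA with main effects only by default (type II sums of
    squares), matching replicate-level repeatability data."""
    v = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (v.shape == fa.shape == fb.shape) or v.ndim != 1:
        raise ValidationError("values and both factors must be equal-length 1-D")
    if len(set(fa.tolist())) < 2 or len(set(fb.tolist())) < 2:
        raise ValidationError("each factor needs at least 2 levels")
    df = pd.DataFrame({"value": v, "fa": fa.astype(str), "fb": fb.astype(str)})
    formula = "value ~ C(fa) + C(fb)" + (" + C(fa):C(fb)" if interaction else "")
    fit = sm.OLS.from_formula(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = float(table.loc["Residual", "df"])
    effects = {}
    term_names = {"C(fa)": names[0], "C(fb)": names[1]}
    if interaction:
        term_names["C(fa):C(fb)"] = f"{names[0]}:{names[1]}"
    for term, pretty in term_names.items():
        ss = float(table.loc[term, "sum_sq"])
        dof = float(table.loc[term, "df"])
        f, p = _guarded_f(ss, dof, resid_ss, resid_df)
        effects[pretty] = FactorEffect(name=pretty, F=f, df=dof, p=p)
    return AnovaResult(effects=effects, residual_df=resid_df)


def one_way_anova_bonferroni(
    groups: dict[str, np.ndarray] | list,
) -> AnovaResult:
    """One-way ANOVA plus all pairwise t comparisons using the pooled
    residual variance, Bonferroni-adjusted (p x m, capped at 1)."""
    if isinstance(groups, dict):
        named = [(str(k), np.asarray(g, dtype=float)) for k, g in groups.items()]
    else:
        named = [(str(i), np.asarray(g, dtype=float)) for i, g in enumerate(groups)]
    if len(named) < 2:
        raise ValidationError("need at least 2 groups")
    for name, g in named:
        if g.size < 2:
            raise ValidationError(f"group {name!r} has n < 2")
    big_n = sum(g.size for _, g in named)
    k = len(named)
    grand = np.concatenate([g for _, g in named]).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for _, g in named)
    ss_within = sum(((g - g.mean()) ** 2).sum() for _, g in named)
    resid_df = big_n - k
    f, p = _guarded_f(ss_between, k - 1, ss_within, resid_df)
    effects = {"group": FactorEffect(name="group", F=f, df=float(k - 1), p=p)}
    mse = ss_within / resid_df if resid_df > 0 else 0.0
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        (na, ga), (nb, gb) = named[i], named[j]
        diff = float(ga.mean() - gb.mean())
        se = np.sqrt(mse * (1.0 / ga.size + 1.0 / gb.size))
        if se == 0:
            t = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
            raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            raw = float(2.0 * stats.t.sf(abs(t), resid_df))
        pairwise.append(
            PairwiseComparison(
                group_a=na, group_b=nb, difference=diff, t=float(t),
                p_raw=raw, p_adjusted=min(1.0, m * raw),
            )
        )
    return AnovaResult(effects=effects, residual_df=float(resid_df), pairwise=pairwise)


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t test; returns ``(t, p)`` with n-1 df."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D")
    if x.size < 2:
        raise ValidationError("paired t test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("paired differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), d.size - 1))
    return t, p


def normality_test(values) -> tuple[float, float]:
    """D'Agostino-Pearson K^2 omnibus test; returns ``(K2, p)``.

    Requires n >= 20 (the kurtosis z approximation breaks below that).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 20:
        raise SampleSizeError("normality test requires n >= 20")
    k2, p = stats.normaltest(v)
    return float(k2), float(p)
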