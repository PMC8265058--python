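"""Agreement, diagnostic and group-comparison statistics.

The battery mirrors what observer-agreement studies of quantitative
imaging indices report: intraclass correlation (two-way random effects,
absolute agreement, single measurement — ICC(2,1)), Bland--Altman bias
and limits of agreement, Fleiss' kappa for categorical concordance,
empirical ROC with the Youden operating point, sensitivity / specificity
/ predictive values with exact (Clopper--Pearson) binomial confidence
intervals, and rank-based / t / correlation tests for group structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "MetricWithCI",
    "icc_absolute_agreement",
    "bland_altman",
    "roc_auc_and_youden",
    "fleiss_kappa",
    "diagnostic_metrics",
    "clopper_pearson_interval",
    "rank_sum_test",
    "welch_t_test",
    "pearson_corr",
    "group_tests",
]


class DegenerateDataError(ValueError):
    """Statistic undefined for the supplied data (zero variance etc.)."""


@dataclass(frozen=True)
class MetricWithCI:
    value: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not np.isnan(self.value):
            assert self.ci_lower - 1e-12 <= self.value <= self.ci_upper + 1e-12

    def to_dict(self) -> dict:
        return {"value": self.value, "ci95": [self.ci_lower, self.ci_upper]}


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float

    def __post_init__(self) -> None:
        assert self.loa_lower - 1e-12 <= self.bias <= self.loa_upper + 1e-12


@dataclass
class AgreementReport:
    """Container for the full agreement battery of one comparison."""

    icc: MetricWithCI | None = None
    bland_altman: BlandAltman | None = None
    kappa: float | None = None
    auc: float | None = None
    youden_threshold: float | None = None
    youden_j: float | None = None
    diagnostics: dict[str, MetricWithCI] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.icc is not None:
            out["icc"] = self.icc.to_dict()
        if self.bland_altman is not None:
            ba = self.bland_altman
            out["bland_altman"] = {
                "bias": ba.bias,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
            }
        if self.kappa is not None:
            out["fleiss_kappa"] = self.kappa
        if self.auc is not None:
            out["roc"] = {
                "auc": self.auc,
                "youden_threshold": self.youden_threshold,
                "youden_j": self.youden_j,
            }
        if self.diagnostics:
            out["diagnostics"] = {k: v.to_dict() for k, v in self.diagnostics.items()}
        return out


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def icc_absolute_agreement(
    measurements: np.ndarray, alpha: float = 0.05
) -> MetricWithCI:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is (n_subjects, k_raters).  Variance components come
    from the two-way ANOVA mean squares; the confidence interval uses the
    standard F-distribution bounds (Shrout & Fleiss; McGraw & Wong).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateDataError("need >= 2 subjects and >= 2 raters")
    n, k = x.shape
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero total variance; ICC undefined")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateDataError("degenerate variance structure")
    icc = (msr - mse) / denom

    # F-based CI for ICC(A,1); guards for perfect agreement (mse == 0)
    if mse <= 0:
        return MetricWithCI(float(icc), float(icc), float(icc))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (
        (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    )
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (
        n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    v = vn / vd
    f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msr
    )
    lower = min(lower, icc)
    upper = max(upper, icc)
    return MetricWithCI(float(icc), float(max(-1.0, lower)), float(min(1.0, upper)))


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltman:
    """Bias and 95% limits of agreement (bias +/- 1.96 * sample SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DegenerateDataError("need >= 3 paired measurements")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd)


def fleiss_kappa(ratings: np.ndarray, n_categories: int | None = None) -> float:
    """Fleiss' kappa for ``(n_subjects, n_raters)`` categorical ratings."""
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as _fleiss

    r = np.asarray(ratings)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise DegenerateDataError("need >= 2 subjects and >= 2 raters")
    table, _ = aggregate_raters(r, n_cat=n_categories)
    if table.shape[1] < 2:  # unanimous single category across all subjects
        return 1.0
    p_j = table.sum(axis=0) / table.sum()
    if np.isclose((p_j**2).sum(), 1.0):  # chance agreement saturates
        return 1.0
    return float(_fleiss(table, method="fleiss"))


# ---------------------------------------------------------------------------
# ROC / diagnostics
# ---------------------------------------------------------------------------

def roc_auc_and_youden(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Empirical ROC AUC and the Youden-optimal threshold.

    AUC is the trapezoid area under the empirical ROC (equal to the
    concordant-pair fraction with ties counted half).  The threshold
    maximizes J = sensitivity + specificity - 1 over observed thresholds,
    ties broken toward the higher threshold.  Returns
    ``(auc, threshold, J)``.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.size == 0:
        raise DegenerateDataError("scores and labels must align")
    if len(np.unique(labels)) != 2:
        raise DegenerateDataError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))  # thresholds descend: first max = highest thr
    thr = float(thresholds[best])
    if np.isinf(thr):
        thr = float(scores.max())
    return auc, thr, float(j[best])


def clopper_pearson_interval(
    successes: int, trials: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact binomial CI by beta-quantile inversion of the binomial CDF."""
    if trials == 0:
        return 0.0, 1.0
    lo = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    hi = 1.0 if successes == trials else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lo, hi


def diagnostic_metrics(
    tp: int, fp: int, tn: int, fn: int, alpha: float = 0.05
) -> dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV, NPV with exact 95% CIs.

    A metric with a zero denominator is reported as NaN with CI [0, 1].
    """
    for v in (tp, fp, tn, fn):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be nonnegative integers")

    def metric(x: int, n: int) -> MetricWithCI:
        if n == 0:
            return MetricWithCI(float("nan"), 0.0, 1.0)
        lo, hi = clopper_pearson_interval(x, n, alpha)
        return MetricWithCI(x / n, lo, hi)

    return {
        "sensitivity": metric(tp, tp + fn),
        "specificity": metric(tn, tn + fp),
        "ppv": metric(tp, tp + fp),
        "npv": metric(tn, tn + fn),
    }


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample rank test (Mann--Whitney U), exact for combined n <= 20.

    Returns (U statistic, two-sided p).  Observer-study tables often
    label their independent-group comparison a signed-rank test; for two
    independent groups the rank-sum test is the coherent procedure and is
    what this function computes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DegenerateDataError("need >= 3 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateDataError("constant inputs; rank test undefined")
    method = "exact" if (a.size + b.size) <= 20 and not _has_ties(a, b) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample t-test without the equal-variance assumption."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DegenerateDataError("need >= 3 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateDataError("constant inputs; t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("constant inputs; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_tests(
    values_by_group: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[str, dict[str, float]]:
    """Pairwise rank-sum and Welch-t comparisons between groups.

    By default adjacent pairs in the mapping's order are compared
    (matching the usual cohort-table layout of group A vs B, B vs C).
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise DegenerateDataError("need >= 2 groups")
    if pairs is None:
        pairs = list(zip(names[:-1], names[1:]))
    out: dict[str, dict[str, float]] = {}
    for a_name, b_name in pairs:
        a, b = values_by_group[a_name], values_by_group[b_name]
        u, p_rank = rank_sum_test(a, b)
        t, p_t = welch_t_test(a, b)
        out[f"{a_name}_vs_{b_name}"] = {
            "rank_sum_U": u,
            "rank_sum_p": p_rank,
            "welch_t": t,
            "welch_p": p_t,
            "mean_a": float(np.mean(a)),
            "mean_b": float(np.mean(b)),
        }
    return out
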