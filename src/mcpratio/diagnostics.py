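"""Diagnostic-evaluation statistics for the MCP sT1w/T2w biomarker.

Implements the statistical machinery of the biomarker evaluation: empirical
ROC curves with DeLong variance and the closest-to-upper-left-corner cutoff,
confusion-table metrics with exact (Clopper-Pearson) confidence intervals,
exact binomial accuracy comparisons, the intraclass correlation coefficient,
the Smirnov-Grubbs outlier test, and the group-comparison suite (ANCOVA with
age, Kruskal-Wallis with Bonferroni-corrected exact Mann-Whitney post-hocs,
chi-square, Spearman/Pearson correlations).

Conventions (documented, since the original analyses leave them unstated):

* For the ratio and the normalized volume the *lower* score indicates
  disease; the ``direction`` flag makes this explicit and configurable.
* ROC thresholds sit at midpoints between distinct scores; tied scores
  contribute half-steps to both axes, so the trapezoid AUC equals the
  tie-corrected Mann-Whitney probability.
* Proportion CIs are Clopper-Pearson (exact beta quantiles).
* The binomial accuracy comparison is one-sided (lower tail) by default,
  with the minimum-likelihood two-sided variant available.
* The ICC defaults to the two-way random-effects, absolute-agreement,
  single-measure form (ICC(2,1)); two-way mixed consistency (ICC(3,1)) is
  optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference


class DiagnosticsError(ValueError):
    """Raised on invalid diagnostic-analysis input."""


class DegenerateVarianceError(DiagnosticsError):
    """Raised when a variance needed for a test is (numerically) zero."""


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Empirical ROC curve with DeLong AUC inference.

    ``thresholds`` are in original score units and ordered so that TPR/FPR
    are nondecreasing along the curve, which runs from (0, 0) to (1, 1);
    for ``direction="lower"`` a subject is called diseased when its score is
    <= the threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    direction: str


def _prepare_scores(scores, labels, direction: str):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise DiagnosticsError("scores and labels must have the same length")
    if labels.all() or not labels.any():
        raise DiagnosticsError("ROC analysis needs both classes present")
    if direction not in ("lower", "higher"):
        raise DiagnosticsError("direction must be 'lower' or 'higher'")
    oriented = -scores if direction == "lower" else scores
    return oriented, labels


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Structural components V10 (per diseased) and V01 (per non-diseased).

    V10[i] is the fraction of non-diseased scored below pos[i] (+ half the
    ties); the AUC is the mean of either component vector.
    """
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0)


def roc_auc(scores, labels, direction: str = "lower") -> RocResult:
    """Empirical ROC over all distinct thresholds with DeLong AUC SE.

    The trapezoid AUC equals the tie-corrected pairwise-comparison
    probability P(score_diseased beats score_healthy) + 0.5 P(tie).
    """
    oriented, lab = _prepare_scores(scores, labels, direction)
    pos, neg = oriented[lab], oriented[~lab]

    distinct = np.unique(oriented)[::-1]          # descending
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    cut = np.concatenate([[np.inf], mids, [-np.inf]])
    tpr = (pos[None, :] >= cut[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= cut[:, None]).mean(axis=1)

    v10, v01 = _delong_components(pos, neg)
    auc = float(v10.mean())
    m, n = pos.size, neg.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    ci = (float(np.clip(auc - 1.96 * se, 0.0, 1.0)),
          float(np.clip(auc + 1.96 * se, 0.0, 1.0)))

    thresholds = -cut if direction == "lower" else cut
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     auc_se=se, ci95=ci, direction=direction)


def auc_ci(scores, labels, direction: str = "lower",
           alpha: float = 0.05) -> tuple[float, float]:
    """DeLong normal-approximation CI for a single AUC, truncated to [0, 1]."""
    res = roc_auc(scores, labels, direction)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return (float(np.clip(res.auc - z * res.auc_se, 0.0, 1.0)),
            float(np.clip(res.auc + z * res.auc_se, 0.0, 1.0)))


def delong(scores_a, scores_b, labels, direction: str = "lower"
           ) -> tuple[float, float]:
    """DeLong test comparing two correlated AUCs on paired scores.

    Returns (z, p) for the two-sided normal test of AUC_A = AUC_B using the
    structural-components variance/covariance.
    """
    a, lab = _prepare_scores(scores_a, labels, direction)
    b, _ = _prepare_scores(scores_b, labels, direction)
    v10a, v01a = _delong_components(a[lab], a[~lab])
    v10b, v01b = _delong_components(b[lab], b[~lab])
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size
    if m < 2 or n < 2:
        raise DiagnosticsError("DeLong comparison needs >= 2 per class")
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        if abs(diff) <= 1e-12:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            f"zero variance for a nonzero AUC difference ({diff:.4f}); "
            "the paired scores are too degenerate for the normal test")
    z = float(diff / np.sqrt(var_diff))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


@dataclass
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float


def optimal_cutoff(roc: RocResult) -> CutoffResult:
    """Operating point closest to the upper-left ROC corner (FPR 0, TPR 1).

    Minimizes sqrt((1 - TPR)^2 + FPR^2) over the finite thresholds; ties are
    broken toward higher specificity, then toward the lower threshold.
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise DiagnosticsError("ROC curve has no finite thresholds")
    thr, tpr, fpr = roc.thresholds[finite], roc.tpr[finite], roc.fpr[finite]
    dist = np.hypot(1.0 - tpr, fpr)
    best = dist <= dist.min() + 1e-12
    idx = np.flatnonzero(best)
    idx = idx[fpr[idx] <= fpr[idx].min() + 1e-12]
    i = idx[np.argmin(thr[idx])]
    return CutoffResult(threshold=float(thr[i]), sensitivity=float(tpr[i]),
                        specificity=float(1.0 - fpr[i]))


# ---------------------------------------------------------------------------
# Confusion tables and exact proportion CIs
# ---------------------------------------------------------------------------

def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided CI for a binomial proportion."""
    if n < 1 or not 0 <= x <= n:
        raise DiagnosticsError(f"invalid counts x={x}, n={n}")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lo, hi


@dataclass
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if int(v) != v or v < 0:
                raise DiagnosticsError("confusion counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricEstimate:
    """A percent point estimate with its exact CI (percent)."""

    pct: float
    ci_lo_pct: float
    ci_hi_pct: float


@dataclass
class DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV/accuracy in percent with exact CIs.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    accuracy: MetricEstimate | None


def _metric(x: int, n: int, alpha: float) -> MetricEstimate | None:
    if n == 0:
        return None
    lo, hi = clopper_pearson(x, n, alpha)
    return MetricEstimate(pct=100.0 * x / n, ci_lo_pct=100.0 * lo,
                          ci_hi_pct=100.0 * hi)


def confusion_metrics(table: ConfusionTable, alpha: float = 0.05
                      ) -> DiagnosticSummary:
    """The five diagnostic metrics in percent with Clopper-Pearson CIs."""
    t = table
    return DiagnosticSummary(
        sensitivity=_metric(t.tp, t.tp + t.fn, alpha),
        specificity=_metric(t.tn, t.tn + t.fp, alpha),
        ppv=_metric(t.tp, t.tp + t.fp, alpha),
        npv=_metric(t.tn, t.tn + t.fn, alpha),
        accuracy=_metric(t.tp + t.tn, t.total, alpha),
    )


def binomial_accuracy_test(correct: int, n: int, p0: float,
                           sided: str = "lower") -> float:
    """Exact binomial test of an observed accuracy against a reference rate.

    ``sided="lower"`` returns the lower-tail probability P(X <= correct)
    under Binomial(n, p0); ``sided="two"`` uses the minimum-likelihood
    two-sided method.
    """
    if not 0 <= correct <= n or n < 1:
        raise DiagnosticsError("invalid counts")
    if not 0.0 < p0 < 1.0:
        raise DiagnosticsError("p0 must lie in (0, 1)")
    alternative = {"lower": "less", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise DiagnosticsError("sided must be 'lower' or 'two'")
    return float(stats.binomtest(correct, n, p0, alternative=alternative).pvalue)


# ---------------------------------------------------------------------------
# Inter-reviewer agreement (ICC)
# ---------------------------------------------------------------------------

@dataclass
class IccResult:
    icc: float
    variant: str
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def icc(ratings, variant: str = "icc2_1") -> IccResult:
    """Intraclass correlation from the two-way ANOVA mean squares.

    ``icc2_1``: two-way random effects, absolute agreement, single measure
    (default).  ``icc3_1``: two-way mixed effects, consistency, single
    measure.  ``ratings`` is a complete subjects x raters matrix.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DiagnosticsError("need >= 2 subjects and >= 2 raters")
    if not np.isfinite(x).all():
        raise DiagnosticsError("ratings must be complete (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 1e-14 and mse <= 1e-14:
        return IccResult(float("nan"), variant, n, k, degenerate=True)
    if variant == "icc2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "icc3_1":
        denom = msr + (k - 1) * mse
    else:
        raise DiagnosticsError(f"unknown ICC variant {variant!r}")
    if abs(denom) <= 1e-14:
        return IccResult(float("nan"), variant, n, k, degenerate=True)
    return IccResult(float((msr - mse) / denom), variant, n, k)


# ---------------------------------------------------------------------------
# Smirnov-Grubbs outlier test
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    g_statistic: float
    critical_value: float
    alpha: float
    flagged_index: int | None
    removed_indices: list = field(default_factory=list)


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """t-distribution-based critical value of the single-outlier G statistic."""
    if n < 3:
        raise DiagnosticsError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2)))


def grubbs(values, alpha: float = 0.05, iterative: bool = False) -> OutlierReport:
    """Smirnov-Grubbs test: max studentized deviation vs its critical value.

    Flags the most extreme point when G = max|x - mean| / sd exceeds the
    critical value; with ``iterative=True``, flagged points are removed and
    the reduced series re-tested until no outlier remains.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DiagnosticsError("Grubbs test needs n >= 3")
    if np.std(x, ddof=1) == 0:
        raise DiagnosticsError("Grubbs test is undefined for a constant series")

    active = np.arange(x.size)
    removed: list[int] = []
    while True:
        xs = x[active]
        sd = np.std(xs, ddof=1)
        if xs.size < 3 or sd == 0:
            break
        dev = np.abs(xs - xs.mean())
        g = float(dev.max() / sd)
        crit = grubbs_critical_value(xs.size, alpha)
        flagged = int(active[np.argmax(dev)]) if g > crit else None
        if flagged is None or not iterative:
            return OutlierReport(g, crit, alpha, flagged, removed)
        removed.append(flagged)
        active = active[active != flagged]
    return OutlierReport(float("nan"), float("nan"), alpha, None, removed)


# ---------------------------------------------------------------------------
# Group-comparison suite
# ---------------------------------------------------------------------------

def bonferroni_alpha(n_comparisons: int, alpha: float = 0.05) -> float:
    """Per-comparison significance level after Bonferroni correction."""
    if n_comparisons < 1:
        raise DiagnosticsError("need >= 1 comparison")
    return alpha / n_comparisons


def _ancova_group_test(df: pd.DataFrame, value_col: str, group_col: str,
                       covariate_col: str) -> dict:
    """One-way ANCOVA F-test for group, common covariate slope."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    sub = df[[value_col, group_col, covariate_col]].dropna()
    model = smf.ols(f"{value_col} ~ C({group_col}) + {covariate_col}",
                    data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[f"C({group_col})"]
    return {"F": float(row["F"]), "p": float(row["PR(>F)"]),
            "df_num": float(row["df"]),
            "df_den": float(table.loc["Residual", "df"])}


def group_comparisons(cohort: pd.DataFrame, *,
                      ratio_col: str = "mcp_ratio",
                      volume_col: str = "mcp_volume_norm",
                      group_col: str = "group",
                      age_col: str = "age",
                      sex_col: str = "sex",
                      duration_col: str = "disease_duration",
                      extent_col: str = "extent_score",
                      patient_groups: tuple[str, ...] = ("MSA-C", "SCA3", "SCA6"),
                      index_group: str = "MSA-C",
                      alpha: float = 0.05) -> dict:
    """The cohort-level comparison suite.

    Runs: chi-square on the sex table; one-way ANOVA on age; Kruskal-Wallis
    on disease duration over the patient groups with exact pairwise
    Mann-Whitney post-hocs at the Bonferroni-corrected level; one-way ANCOVA
    (age as covariate) for the ratio and normalized volume; Spearman
    correlation of the hyperintensity-extent score with the ratio and Pearson
    correlation of the ratio with the volume, both within ``index_group``.
    """
    report: dict = {}
    groups = [g for g in cohort[group_col].unique()]
    if any(cohort[cohort[group_col] == g].shape[0] < 2 for g in groups):
        raise DiagnosticsError("each group needs >= 2 subjects")

    pairs = [(a, b) for i, a in enumerate(patient_groups)
             for b in patient_groups[i + 1:]]
    if pairs:
        report["bonferroni_alpha"] = bonferroni_alpha(len(pairs), alpha)

    if sex_col in cohort:
        table = pd.crosstab(cohort[group_col], cohort[sex_col])
        chi2 = stats.chi2_contingency(table.to_numpy())
        report["sex_chi2"] = {"chi2": float(chi2.statistic),
                              "p": float(chi2.pvalue)}

    if age_col in cohort and len(groups) >= 2:
        by_group = [cohort.loc[cohort[group_col] == g, age_col].dropna()
                    for g in groups]
        f, p = stats.f_oneway(*by_group)
        report["age_anova"] = {"F": float(f), "p": float(p)}

    if duration_col in cohort and pairs:
        samples = {g: cohort.loc[cohort[group_col] == g, duration_col].dropna()
                   for g in patient_groups}
        if all(len(s) > 0 for s in samples.values()):
            h, p = stats.kruskal(*samples.values())
            post = {}
            for a, b in pairs:
                xa, xb = samples[a].to_numpy(), samples[b].to_numpy()
                method = ("exact" if max(xa.size, xb.size) <= 25
                          and np.unique(np.concatenate([xa, xb])).size
                          == xa.size + xb.size else "auto")
                mwu = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                         method=method)
                post[f"{a} vs {b}"] = {
                    "U": float(mwu.statistic), "p": float(mwu.pvalue),
                    "significant": bool(mwu.pvalue < report["bonferroni_alpha"]),
                }
            report["duration_kruskal"] = {"H": float(h), "p": float(p)}
            report["duration_pairwise"] = post

    for name, col in (("ratio_ancova", ratio_col), ("volume_ancova", volume_col)):
        if col in cohort and age_col in cohort and len(groups) >= 2:
            report[name] = _ancova_group_test(cohort, col, group_col, age_col)

    index = cohort[cohort[group_col] == index_group]
    if extent_col in cohort and len(index) >= 3:
        rho, p = stats.spearmanr(index[extent_col], index[ratio_col])
        report["spearman_extent_ratio"] = {"r": float(rho), "p": float(p)}
    if volume_col in cohort and len(index) >= 3:
        r, p = stats.pearsonr(index[ratio_col], index[volume_col])
        report["pearson_ratio_volume"] = {"r": float(r), "p": float(p)}
    return report


# ---------------------------------------------------------------------------
# Published-table reconstruction helpers
# ---------------------------------------------------------------------------

def reference_confusion_table(sign: str, comparison: tuple[str, str],
                              reviewer: int) -> ConfusionTable:
    """Confusion table implied by a published sensitivity/specificity cell."""
    sens, spec, *_ = reference.REVIEWER_PERFORMANCE[sign][comparison][reviewer]
    n_pos = reference.GROUP_SIZES[comparison[0]]
    n_neg = reference.GROUP_SIZES[comparison[1]]
    tp, fn, fp, tn = reference.reconstruct_counts(sens, spec, n_pos, n_neg)
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def reviewer_performance_check() -> pd.DataFrame:
    """Recompute every published reviewer-performance percent cell.

    For each sign / comparison / reviewer the confusion table is rebuilt from
    the published sensitivity, specificity and group sizes, the five metrics
    are recomputed, and both values are tabulated.  Cells that are undefined
    (zero denominator) are skipped.  The ``abs_diff`` column should be
    <= 0.05 everywhere (one-decimal agreement).
    """
    rows = []
    metric_names = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
    for sign, by_comp in reference.REVIEWER_PERFORMANCE.items():
        for comparison, by_rev in by_comp.items():
            for reviewer, published in by_rev.items():
                table = reference_confusion_table(sign, comparison, reviewer)
                summary = confusion_metrics(table)
                for name, pub in zip(metric_names, published):
                    est = getattr(summary, name)
                    if pub is None or est is None:
                        continue
                    rows.append({
                        "sign": sign,
                        "comparison": f"{comparison[0]} vs {comparison[1]}",
                        "reviewer": reviewer, "metric": name,
                        "published_pct": pub,
                        "recomputed_pct": est.pct,
                        "abs_diff": abs(est.pct - pub),
                    })
    return pd.DataFrame(rows)
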