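"""Country-level correlations and the old-vs-new instrument comparison.

Country-level prevalence is correlated with national development measures
(HDI, per-capita GNI) by Spearman's rho, and the prevalences derived from
the new 11-item instrument are compared with the previously published
legacy-instrument prevalences via Pearson correlation and a paired t test.
Confidence intervals for both correlation types use the Fisher z
transform with standard error 1/sqrt(n - 3) (no small-sample correction
factor for the Spearman case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    coefficient: float
    ci_low: float
    ci_high: float
    n: int
    method: str
    p_value: float

    def __post_init__(self):
        assert abs(self.coefficient) <= 1.0
        assert self.ci_low - 1e-12 <= self.coefficient <= self.ci_high + 1e-12


@dataclass
class ComparisonReport:
    n_pairs: int
    pearson: CorrelationResult
    mean_new: float
    mean_old: float
    paired_t: float
    df: int
    p_two_sided: float

    def __post_init__(self):
        assert self.df == self.n_pairs - 1


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if abs(r) >= 1.0:          # degenerate: the transform is unbounded
        return float(r), float(r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def spearman_ci(x, y) -> CorrelationResult:
    """Spearman's rho (average ranks for ties) with a Fisher-z 95% CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs for a Fisher-z interval")
    res = stats.spearmanr(x, y)
    lo, hi = _fisher_ci(res.statistic, len(x))
    return CorrelationResult(float(res.statistic), lo, hi, len(x), "spearman",
                             float(res.pvalue))


def pearson_ci(x, y) -> CorrelationResult:
    """Product-moment correlation with a Fisher-z 95% CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs for a Fisher-z interval")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    lo, hi = _fisher_ci(res.statistic, len(x))
    return CorrelationResult(float(res.statistic), lo, hi, len(x), "pearson",
                             float(res.pvalue))


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Paired t on differences x - y: (t, df, two-sided p).

    Zero-variance differences with a nonzero mean yield an infinite t.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def compare_measures(new, old, labels=None) -> ComparisonReport:
    """Bundle correlation, means and paired t for matched prevalence pairs."""
    new, old = np.asarray(new, float), np.asarray(old, float)
    if len(new) < 4:
        raise ValueError("need at least 4 labelled pairs")
    pear = pearson_ci(new, old)
    t, df, p = paired_ttest(new, old)
    return ComparisonReport(
        n_pairs=len(new), pearson=pear,
        mean_new=float(new.mean()), mean_old=float(old.mean()),
        paired_t=t, df=df, p_two_sided=p,
    )


def comparison_text(report: ComparisonReport) -> str:
    return (
        f"{report.n_pairs} matched surveys: new-instrument mean prevalence "
        f"{report.mean_new:.1f}% vs {report.mean_old:.1f}% previously; "
        f"r = {report.pearson.coefficient:.2f} "
        f"(95% CI {report.pearson.ci_low:.2f} to {report.pearson.ci_high:.2f}); "
        f"paired t = {report.paired_t:.2f}, df = {report.df}, "
        f"p = {report.p_two_sided:.4f}"
    )
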