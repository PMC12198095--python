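"""Survey-weighted prevalence estimation and age-trend summaries.

Point estimates are Horvitz-Thompson style weighted proportions.  The 95%
interval is a Wald interval on the logit scale with the Kish effective
sample size n_eff = (sum w)^2 / sum w^2 standing in for the design-based
variance — this produces the asymmetric intervals typical of survey
reports and is invariant to rescaling the weights.  A full
Taylor-linearised cluster variance is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .scd_scoring import CutPointSet, flag_scd
from .survey_io import AGE_YEARS, SurveyTable, assign_age_year

Z975 = stats.norm.ppf(0.975)


@dataclass
class PrevalenceEstimate:
    p_hat: float          # percent
    ci_low: float         # percent
    ci_high: float        # percent
    n: int
    effective_n: float
    label: str = ""
    degenerate: bool = False

    def __post_init__(self):
        assert 0.0 <= self.ci_low <= self.p_hat + 1e-12
        assert self.p_hat <= self.ci_high + 1e-12 and self.ci_high <= 100.0


def kish_effective_n(weights) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w ** 2).sum())


def weighted_prevalence(flags, weights, label: str = "") -> PrevalenceEstimate:
    """Weighted prevalence (percent) with a logit-scale 95% CI.

    Degenerate samples (all true / all false) get a one-sided interval via
    a half-count continuity correction on the effective sample size and
    are flagged.
    """
    f = np.asarray(flags, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(f) == 0:
        raise ValueError("empty input")
    if len(f) != len(w):
        raise ValueError("flags and weights must have the same length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if np.isnan(f).any():
        raise ValueError("flags contain missing values")

    p = float((w * f).sum() / w.sum())
    n_eff = kish_effective_n(w)

    degenerate = p in (0.0, 1.0)
    if degenerate:
        # continuity correction: half a (effective) success either side
        p_adj = np.clip(p, 0.5 / (n_eff + 1), 1 - 0.5 / (n_eff + 1))
    else:
        p_adj = p
    se_logit = np.sqrt(p_adj * (1 - p_adj) / n_eff) / (p_adj * (1 - p_adj))
    lo = float(expit(logit(p_adj) - Z975 * se_logit))
    hi = float(expit(logit(p_adj) + Z975 * se_logit))
    if degenerate:
        lo, hi = (0.0, hi) if p == 0.0 else (lo, 1.0)

    return PrevalenceEstimate(
        p_hat=100 * p, ci_low=100 * min(lo, p), ci_high=100 * max(hi, p),
        n=len(f), effective_n=n_eff, label=label, degenerate=degenerate,
    )


def prevalence_by_country(table: SurveyTable, cuts: CutPointSet) -> pd.DataFrame:
    """Weighted SCD prevalence per country (complete-case children)."""
    flags = flag_scd(table, cuts)
    frame = table.children.assign(scd=flags).dropna(subset=["scd"])
    rows = []
    for code, sub in frame.groupby("country_code"):
        est = weighted_prevalence(sub["scd"], sub["child_weight"], label=str(code))
        rows.append({
            "country_code": code, "prevalence": est.p_hat,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "n": est.n, "effective_n": est.effective_n,
        })
    return pd.DataFrame(rows)


def pooled_prevalence(
    table: SurveyTable,
    grouping: dict[str, str],
    flags: pd.Series | None = None,
    cuts: CutPointSet | None = None,
) -> dict[str, PrevalenceEstimate]:
    """Pool children across countries within groups, weights as provided.

    ``grouping`` maps country_code -> group label; every country present
    must be mapped.  Either precomputed per-child ``flags`` or a
    ``cuts`` set to derive them must be given.
    """
    if flags is None:
        if cuts is None:
            raise ValueError("provide flags or cuts")
        flags = flag_scd(table, cuts)
    frame = table.children.assign(scd=flags).dropna(subset=["scd"])
    unmapped = set(frame["country_code"]) - set(grouping)
    if unmapped:
        raise ValueError(f"countries without a group: {sorted(unmapped)}")
    frame["group"] = frame["country_code"].map(grouping)
    out = {}
    for group, sub in frame.groupby("group"):
        if len(sub) == 0:
            continue
        out[str(group)] = weighted_prevalence(
            sub["scd"], sub["child_weight"], label=str(group)
        )
    return out


def prevalence_ratio(num: PrevalenceEstimate | float, den: PrevalenceEstimate | float) -> float:
    """Ratio of prevalences, rounded to one decimal for reporting."""
    p_num = num.p_hat if isinstance(num, PrevalenceEstimate) else float(num)
    p_den = den.p_hat if isinstance(den, PrevalenceEstimate) else float(den)
    if p_den == 0:
        raise ZeroDivisionError("denominator prevalence is zero")
    return round(p_num / p_den, 1)


def prevalence_by_age(table: SurveyTable, cuts: CutPointSet) -> dict:
    """Country-level SCD prevalence at ages 2, 3, 4 with group summaries.

    Ages map to month ranges 24-35, 36-47, 48-59.  Returns the per-country
    x age table, unweighted across-country means with t-based 95% CIs, and
    paired t statistics between adjacent ages (countries lacking an age,
    e.g. 36-59-month-only surveys, are excluded pairwise).
    """
    flags = flag_scd(table, cuts)
    frame = table.children.assign(scd=flags).dropna(subset=["scd"])
    frame["age_year"] = frame["age_months"].map(assign_age_year)

    records = {}
    for (code, year), sub in frame.groupby(["country_code", "age_year"]):
        est = weighted_prevalence(sub["scd"], sub["child_weight"])
        records.setdefault(code, {})[year] = est.p_hat
    percountry = pd.DataFrame.from_dict(records, orient="index").sort_index()
    percountry = percountry.reindex(columns=sorted(AGE_YEARS))

    means = {}
    for year in percountry.columns:
        vals = percountry[year].dropna()
        m = float(vals.mean())
        half = (stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
                if len(vals) > 1 else np.nan)
        means[year] = {"mean": m, "ci_low": m - half, "ci_high": m + half,
                       "n_countries": int(len(vals))}

    paired = {}
    for y1, y2 in [(2, 3), (3, 4)]:
        both = percountry[[y1, y2]].dropna()
        if len(both) >= 2:
            t, p = stats.ttest_rel(both[y1], both[y2])
            paired[f"{y1}v{y2}"] = {"t": float(t), "df": len(both) - 1, "p": float(p)}
    return {"per_country": percountry, "group_means": means, "paired_t": paired}
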