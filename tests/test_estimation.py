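"""Weighted prevalence, pooling, ratios, age trends, CI calibration."""

import numpy as np
import pytest
from scipy import stats

from scdkit.estimation import (kish_effective_n, pooled_prevalence,
                               prevalence_by_age, prevalence_ratio,
                               weighted_prevalence)
from scdkit.fixtures import table5_pooled
from scdkit.scd_scoring import calibrate_from_survey
from scdkit.survey_io import ITEMS, SurveyTable
from scdkit.synthetic_data import SimConfig, simulate_reference_pool, simulate_survey
from tests.conftest import make_children


def oracle_prevalence(flags, weights):
    """Independent longhand implementation of the same estimator formulas."""
    f, w = np.asarray(flags, float), np.asarray(weights, float)
    p = np.sum(w * f) / np.sum(w)
    n_eff = np.sum(w) ** 2 / np.sum(w ** 2)
    z = stats.norm.ppf(0.975)
    L = np.log(p / (1 - p))
    se = 1.0 / np.sqrt(n_eff * p * (1 - p))
    lo = 1 / (1 + np.exp(-(L - z * se)))
    hi = 1 / (1 + np.exp(-(L + z * se)))
    return 100 * p, 100 * lo, 100 * hi


class TestWeightedPrevalence:
    def test_equal_weights_is_plain_proportion(self):
        flags = np.zeros(100)
        flags[:5] = 1
        est = weighted_prevalence(flags, np.ones(100))
        assert est.p_hat == pytest.approx(5.0)

    def test_weighted_arithmetic(self):
        est = weighted_prevalence([1, 0, 0], [2.0, 1.0, 1.0])
        assert est.p_hat == pytest.approx(50.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(13)
        flags = (rng.random(500) < 0.12).astype(float)
        w = rng.lognormal(0, 0.7, 500)
        est = weighted_prevalence(flags, w)
        p, lo, hi = oracle_prevalence(flags, w)
        assert est.p_hat == pytest.approx(p, abs=1e-10)
        assert est.ci_low == pytest.approx(lo, abs=1e-10)
        assert est.ci_high == pytest.approx(hi, abs=1e-10)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(14)
        flags = (rng.random(200) < 0.3).astype(float)
        w = rng.uniform(0.2, 5, 200)
        a, b = weighted_prevalence(flags, w), weighted_prevalence(flags, 13 * w)
        assert (a.p_hat, a.ci_low, a.ci_high) == pytest.approx(
            (b.p_hat, b.ci_low, b.ci_high))

    def test_degenerate_all_false_flagged(self):
        est = weighted_prevalence(np.zeros(50), np.ones(50))
        assert est.degenerate and est.p_hat == 0.0 and est.ci_low == 0.0
        assert est.ci_high > 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_prevalence([], [])

    def test_ci_coverage_with_informative_weights(self):
        # binary outcome correlated with the sampling weight; sample is half
        # per stratum while weights imply a 25/75 population split
        rng = np.random.default_rng(15)
        p_true = 100 * (0.25 * 0.15 + 0.75 * 0.05)
        reps, n, hits = 1000, 400, 0
        for _ in range(reps):
            strata = rng.integers(0, 2, n)
            p = np.where(strata == 1, 0.15, 0.05)
            w = np.where(strata == 1, 0.5, 1.5)      # inverse selection prob
            flags = (rng.random(n) < p).astype(float)
            est = weighted_prevalence(flags, w)
            hits += est.ci_low <= p_true <= est.ci_high
        assert 0.92 <= hits / reps <= 0.98


class TestPooling:
    def _survey(self, specs):
        rows = []
        for code, p, w, n in specs:
            for i in range(n):
                scd_items = {it: 0.0 for it in ITEMS} if i < p * n else \
                            {it: 1.0 for it in ITEMS}
                rows.append({"country_code": code, "child_weight": w, **scd_items})
        return SurveyTable(make_children(rows))

    def test_single_country_group_equals_country_estimate(self):
        table = self._survey([("AA", 0.1, 1.0, 50)])
        from scdkit.scd_scoring import CutPointSet, TargetRange
        cuts = CutPointSet({"36-41": 0}, {}, TargetRange())
        pooled = pooled_prevalence(table, {"AA": "g"}, cuts=cuts)
        est = weighted_prevalence(
            (table.children[ITEMS].sum(axis=1) == 0).astype(float),
            table.children["child_weight"])
        assert pooled["g"].p_hat == pytest.approx(est.p_hat)

    def test_two_equal_countries_average(self):
        table = self._survey([("AA", 0.02, 1.0, 100), ("BB", 0.06, 1.0, 100)])
        from scdkit.scd_scoring import CutPointSet, TargetRange
        cuts = CutPointSet({"36-41": 0}, {}, TargetRange())
        pooled = pooled_prevalence(table, {"AA": "g", "BB": "g"}, cuts=cuts)
        assert pooled["g"].p_hat == pytest.approx(4.0)

    def test_pooling_associative(self, default_survey):
        cuts, _ = calibrate_from_survey(default_survey)
        meta = default_survey.meta
        by_group = dict(zip(meta["country_code"], meta["hdi_group"]))
        all_one = {c: "all" for c in meta["country_code"]}
        direct = pooled_prevalence(default_survey, all_one, cuts=cuts)["all"]
        # pool the group-level children manually: same children, same weights
        groups = pooled_prevalence(default_survey, by_group, cuts=cuts)
        from scdkit.scd_scoring import flag_scd
        flags = flag_scd(default_survey, cuts)
        ch = default_survey.children.assign(scd=flags).dropna(subset=["scd"])
        p_manual = 100 * (ch["scd"] * ch["child_weight"]).sum() / ch["child_weight"].sum()
        assert direct.p_hat == pytest.approx(p_manual, abs=1e-10)
        # group-weighted recombination reproduces the direct pooled estimate
        ch["group"] = ch["country_code"].map(by_group)
        wsum = ch.groupby("group")["child_weight"].sum()
        recombined = sum(groups[g].p_hat * wsum[g] for g in groups) / wsum.sum()
        assert recombined == pytest.approx(direct.p_hat, abs=1e-9)

    def test_gradient_increases_across_hdi_groups(self, default_survey):
        cuts, _ = calibrate_from_survey(default_survey)
        meta = default_survey.meta
        grouping = dict(zip(meta["country_code"], meta["hdi_group"]))
        pooled = pooled_prevalence(default_survey, grouping, cuts=cuts)
        order = ["very_high", "high", "medium", "low"]
        vals = [pooled[g].p_hat for g in order]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_unmapped_country_rejected(self, default_survey):
        cuts, _ = calibrate_from_survey(default_survey)
        with pytest.raises(ValueError, match="without a group"):
            pooled_prevalence(default_survey, {"C01": "g"}, cuts=cuts)


class TestRatios:
    def test_published_pooled_ratios(self):
        t5 = table5_pooled()
        assert prevalence_ratio(t5.loc["total", "low"],
                                t5.loc["total", "very_high"]) == 7.0
        assert prevalence_ratio(t5.loc["enrolled", "low"],
                                t5.loc["enrolled", "very_high"]) == 5.3

    def test_self_ratio_is_one(self):
        assert prevalence_ratio(4.2, 4.2) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            prevalence_ratio(5.0, 0.0)


class TestAgeTrends:
    def test_flat_structure_stays_flat(self, default_survey):
        # generator ability growth matches the calibration, so group mean
        # prevalence should not drift with age beyond noise
        cuts, _ = calibrate_from_survey(default_survey)
        res = prevalence_by_age(default_survey, cuts)
        means = [res["group_means"][y]["mean"] for y in (2, 3, 4)]
        halfwidths = [res["group_means"][y]["mean"] - res["group_means"][y]["ci_low"]
                      for y in (2, 3, 4)]
        assert abs(means[0] - means[2]) < halfwidths[0] + halfwidths[2]

    def test_widening_deficit_increases_with_age(self):
        # score growth slower than the reference calibration: SCD rises with age
        lagged = simulate_survey(SimConfig(seed=3, age_slope=0.015))
        pool = simulate_reference_pool(SimConfig(seed=3))
        cuts, _ = calibrate_from_survey(pool)
        res = prevalence_by_age(lagged, cuts)
        means = [res["group_means"][y]["mean"] for y in (2, 3, 4)]
        assert means[0] < means[1] < means[2]
        assert res["paired_t"]["2v3"]["t"] < 0

def test_kish_effective_n_equal_weights():
    assert kish_effective_n(np.full(37, 2.5)) == pytest.approx(37.0)
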