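"""Learning score, cumulative table, cut-point calibration, classification."""

import numpy as np
import pandas as pd
import pytest

from scdkit.fixtures import table3_cumulative
from scdkit.scd_scoring import (CutPointSet, TargetRange, calibrate_cutpoints,
                                calibrate_from_survey, classify_scd,
                                cumulative_pass_table, flag_scd, learning_score,
                                read_cutpoints, write_cutpoints)
from scdkit.survey_io import ITEMS, SurveyTable
from tests.conftest import make_children


def cumtable_from_rows(rows: dict) -> pd.DataFrame:
    """Build a one-band cumulative table from {k: percent} (rest censored)."""
    data = {k: rows.get(k, np.nan) for k in range(12)}
    frame = pd.DataFrame([data], index=["36-41"])
    frame.index.name = "age_band"
    return frame


class TestLearningScore:
    def test_extremes(self):
        assert learning_score([1.0] * 11) == 11
        assert learning_score([0.0] * 11) == 0

    def test_missing_item_incomplete(self):
        vals = [1.0] * 11
        vals[4] = np.nan
        assert np.isnan(learning_score(vals))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            learning_score([1.0] * 10)


class TestCumulativeTable:
    def _table(self, scores, weights, age=38):
        rows = []
        for s, w in zip(scores, weights):
            items = {it: (1.0 if j < s else 0.0) for j, it in enumerate(ITEMS)}
            rows.append({"age_months": age, "child_weight": w, **items})
        return SurveyTable(make_children(rows))

    def test_uniform_counting(self):
        table = self._table(range(10), [1.0] * 10)
        ct = cumulative_pass_table(table)
        assert ct.loc["36-41", 0] == pytest.approx(10.0)
        assert ct.loc["36-41", 4] == pytest.approx(50.0)
        assert ct.loc["36-41", 11] == pytest.approx(100.0)

    def test_weighted_counts_match_brute_force(self):
        table = self._table([0, 1, 1], [1.0, 1.0, 2.0])
        ct = cumulative_pass_table(table)
        assert ct.loc["36-41", 0] == pytest.approx(25.0)
        assert ct.loc["36-41", 1] == pytest.approx(100.0)

    def test_monotone_in_k(self, reference_pool):
        ct = cumulative_pass_table(reference_pool)
        vals = ct[list(range(12))].to_numpy()
        assert (np.diff(vals, axis=1) >= -1e-12).all()
        assert np.allclose(vals[:, -1], 100.0)

    def test_single_band_input_tabulates_that_band_only(self):
        ct = cumulative_pass_table(self._table(range(10), [1.0] * 10))
        assert list(ct.index) == ["36-41"]

    def test_interior_empty_band_named(self):
        # children at 26 and 50 months but nothing between: the 30-35 band
        # lies inside the observed age range yet has no children
        young = self._table(range(5), [1.0] * 5, age=26).children
        old = self._table(range(5), [1.0] * 5, age=50).children
        table = SurveyTable(pd.concat([young, old], ignore_index=True))
        with pytest.raises(ValueError, match="30-35"):
            cumulative_pass_table(table)

    def test_unknown_reference_country_rejected(self, reference_pool):
        with pytest.raises(ValueError, match="ZZ"):
            cumulative_pass_table(reference_pool, ["ZZ"])


class TestCalibration:
    def test_published_table_reproduces_study_cutpoints(self):
        cuts = calibrate_cutpoints(table3_cumulative())
        assert cuts.cuts == {"24-29": 0, "30-35": 0, "36-41": 2, "42-47": 2, "48-59": 4}
        # youngest band (5.3%) is selected by the nearest-to-interval fallback
        assert cuts.fallback_bands == ["24-29"]

    def test_unique_in_range_value_selected(self):
        cuts = calibrate_cutpoints(cumtable_from_rows({0: 1.0, 1: 4.0, 2: 9.0}))
        assert cuts.cuts["36-41"] == 1

    def test_fallback_picks_nearest(self):
        cuts = calibrate_cutpoints(cumtable_from_rows({0: 6.0, 1: 8.0}))
        assert cuts.cuts["36-41"] == 0
        assert cuts.fallback_bands == ["36-41"]

    def test_fallback_tie_prefers_smaller_k(self):
        cuts = calibrate_cutpoints(cumtable_from_rows({0: 2.0, 1: 6.0}))
        assert cuts.cuts["36-41"] == 0

    def test_largest_in_range_k_wins(self):
        cuts = calibrate_cutpoints(cumtable_from_rows({0: 3.2, 1: 4.9, 2: 8.0}))
        assert cuts.cuts["36-41"] == 1

    def test_degenerate_full_target_selects_top(self):
        ct = cumtable_from_rows({k: float(k * 9) for k in range(11)} | {11: 100.0})
        cuts = calibrate_cutpoints(ct, TargetRange(0.0, 100.0))
        assert cuts.cuts["36-41"] == 11

    def test_roundtrip_serialization(self, tmp_path, reference_pool):
        cuts, _ = calibrate_from_survey(reference_pool)
        path = tmp_path / "cuts.txt"
        write_cutpoints(cuts, path)
        again = read_cutpoints(path)
        assert again.cuts == cuts.cuts
        assert again.target == cuts.target
        assert again.achieved == pytest.approx(cuts.achieved)


class TestClassification:
    CUTS = CutPointSet({"24-29": 0, "30-35": 0, "36-41": 2, "42-47": 2, "48-59": 4},
                       {}, TargetRange())

    def test_threshold_semantics(self):
        assert classify_scd(4, "48-59", self.CUTS)
        assert not classify_scd(5, "48-59", self.CUTS)

    def test_zero_score_always_flagged(self):
        for band in self.CUTS.cuts:
            assert classify_scd(0, band, self.CUTS)

    def test_incomplete_score_rejected(self):
        with pytest.raises(ValueError):
            classify_scd(np.nan, "36-41", self.CUTS)

    def test_monotone_in_score(self):
        scores = np.arange(12)
        flags = classify_scd(scores, "42-47", self.CUTS)
        assert (np.diff(flags.astype(int)) <= 0).all()


class TestSelfConsistency:
    def test_achieved_proportions_replay_exactly(self, reference_pool):
        cuts, _ = calibrate_from_survey(reference_pool)
        flags = flag_scd(reference_pool, cuts)
        ch = reference_pool.children.assign(scd=flags).dropna(subset=["scd"])
        from scdkit.survey_io import assign_age_band, band_label
        ch["band"] = ch["age_months"].map(lambda a: band_label(assign_age_band(a)))
        for band, k in cuts.cuts.items():
            sub = ch[ch["band"] == band]
            p = 100.0 * (sub["scd"] * sub["child_weight"]).sum() / sub["child_weight"].sum()
            assert p == pytest.approx(cuts.achieved[band], abs=1e-9)

    def test_reference_pool_achieves_target_range(self, reference_pool):
        cuts, _ = calibrate_from_survey(reference_pool)
        assert cuts.fallback_bands == []
        for band, p in cuts.achieved.items():
            assert 3.0 <= round(p, 1) <= 5.0
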