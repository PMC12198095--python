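"""Summed learning score, cumulative pass-rate table, cut-point calibration
and SCD classification.

The instrument: a child's learning score is the number of the 11 items
passed (defined only when all 11 are answered).  In a pool of reference
countries with high / very-high human development, the weighted cumulative
proportion of children passing at most k items is tabulated per age band,
and the cut-point k* for each band is the largest k whose cumulative
proportion falls in a target range (3-5% by default) — chosen so the
indicator flags roughly the share of children expected to have significant
cognitive delay in well-off settings.  A child is classified SCD when
score <= k* for their band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey_io import AGE_BANDS, ITEMS, SurveyTable, assign_age_band, band_label

N_ITEMS = len(ITEMS)


@dataclass(frozen=True)
class TargetRange:
    """Calibration target range in percent (default 3-5%)."""
    lo: float = 3.0
    hi: float = 5.0

    def __post_init__(self):
        if not (0.0 <= self.lo < self.hi <= 100.0):
            raise ValueError(f"invalid target range [{self.lo}, {self.hi}]")


@dataclass
class CutPointSet:
    """Calibrated per-band thresholds with full provenance."""
    cuts: dict[str, int]
    achieved: dict[str, float]            # percent at the selected k, per band
    target: TargetRange
    reference_countries: list[str] = field(default_factory=list)
    fallback_bands: list[str] = field(default_factory=list)

    def __getitem__(self, band: str) -> int:
        return self.cuts[band]


def learning_score(item_values) -> float:
    """Number of items passed; NaN (incomplete) if any item is missing."""
    v = np.asarray(item_values, dtype=float)
    if v.shape[-1] != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item values, got {v.shape[-1]}")
    if np.isnan(v).any():
        return float("nan")
    return float(v.sum())


def score_children(table: SurveyTable) -> pd.Series:
    """Vectorised learning scores for every child (NaN where incomplete)."""
    items = table.children[ITEMS]
    scores = items.sum(axis=1)
    scores[items.isna().any(axis=1)] = np.nan
    return scores.rename("learning_score")


def cumulative_pass_table(
    table: SurveyTable, reference: list[str] | None = None
) -> pd.DataFrame:
    """Weighted pooled cumulative proportions P(score <= k), percent.

    One row per age band, columns k = 0..11; an ``effective_n`` column
    holds the (unweighted) number of complete-case children per band.
    Children from countries outside ``reference`` (when given) are
    excluded.  Bands entirely outside the observed age range (e.g. for a
    36-59-month-only survey) are omitted; a band inside the observed range
    with no children raises an error naming the band.
    """
    frame = table.children.copy()
    if reference is not None:
        present = set(frame["country_code"])
        absent = [c for c in reference if c not in present]
        if absent:
            raise ValueError(f"reference countries absent from data: {absent}")
        frame = frame[frame["country_code"].isin(reference)]
    frame = frame.dropna(subset=ITEMS)
    frame["score"] = frame[ITEMS].sum(axis=1).astype(int)
    frame["band"] = frame["age_months"].map(lambda a: band_label(assign_age_band(a)))

    age_lo, age_hi = frame["age_months"].min(), frame["age_months"].max()
    rows = {}
    n_col = {}
    for band in AGE_BANDS:
        label = band_label(band)
        if band[1] < age_lo or band[0] > age_hi:
            continue
        sub = frame[frame["band"] == label]
        if len(sub) == 0:
            raise ValueError(f"no complete-case children in age band {label}")
        w = sub["child_weight"].to_numpy(float)
        mass = np.bincount(sub["score"].to_numpy(int), weights=w, minlength=N_ITEMS + 1)
        rows[label] = 100.0 * np.cumsum(mass) / w.sum()
        n_col[label] = len(sub)

    out = pd.DataFrame.from_dict(rows, orient="index", columns=range(N_ITEMS + 1))
    out.index.name = "age_band"
    out.columns.name = "items_passed"
    out["effective_n"] = pd.Series(n_col)
    return out


def calibrate_cutpoints(
    cumtable: pd.DataFrame,
    target: TargetRange = TargetRange(),
    reference: list[str] | None = None,
) -> CutPointSet:
    """Select per-band cut-points against the target range.

    Proportions are rounded to one decimal (as printed) before the
    in-range test; the largest in-range k wins.  If no k qualifies, the k
    nearest to the interval (distance to the closer endpoint, smaller k on
    ties) is selected — censored cells (NaN, published only as ">10%") are
    never selectable.
    """
    cuts, achieved, fallback = {}, {}, []
    k_cols = [c for c in cumtable.columns if isinstance(c, (int, np.integer))]
    for band, row in cumtable.iterrows():
        props = row[k_cols]
        rounded = props.round(1)
        in_range = rounded[(rounded >= target.lo) & (rounded <= target.hi)].dropna()
        if len(in_range):
            k = int(max(in_range.index))
        else:
            valid = rounded.dropna()
            if valid.empty:
                raise ValueError(f"band {band} has no uncensored proportions")
            vals = valid.to_numpy(float)
            dist = np.maximum(np.maximum(target.lo - vals, vals - target.hi), 0.0)
            k = int(valid.index[int(np.argmin(dist))])  # first minimum = smallest k on ties
            fallback.append(str(band))
        cuts[str(band)] = k
        achieved[str(band)] = float(props[k])
    return CutPointSet(cuts, achieved, target, list(reference or []), fallback)


def classify_scd(score, band, cuts: CutPointSet):
    """SCD flag: score <= k* for the child's age band.

    ``score`` may be scalar or array; incomplete (NaN) scores raise — the
    caller must apply the complete-case filter first.
    """
    s = np.asarray(score, dtype=float)
    if np.isnan(s).any():
        raise ValueError("incomplete learning score: filter complete cases first")
    label = band if isinstance(band, str) else band_label(band)
    return s <= cuts[label]


def flag_scd(table: SurveyTable, cuts: CutPointSet) -> pd.Series:
    """Per-child SCD flags for complete-case children (NaN elsewhere)."""
    scores = score_children(table)
    bands = table.children["age_months"].map(lambda a: band_label(assign_age_band(a)))
    k_star = bands.map(cuts.cuts)
    flags = (scores <= k_star).astype(float)
    flags[scores.isna()] = np.nan
    return flags.rename("scd")


def calibrate_from_survey(
    table: SurveyTable,
    target: TargetRange = TargetRange(),
    reference: list[str] | None = None,
) -> tuple[CutPointSet, pd.DataFrame]:
    """Full calibration: pool reference countries, tabulate, select cuts.

    When ``reference`` is None the reference pool is all countries whose
    metadata puts them in the very-high or high HDI groups.
    """
    if reference is None:
        if table.meta is None:
            raise ValueError("no reference list and no country metadata")
        meta = table.meta
        reference = sorted(meta.loc[meta["hdi_group"].isin(["very_high", "high"]),
                                    "country_code"])
        if not reference:
            raise ValueError("no very-high or high HDI countries in metadata")
    cumtable = cumulative_pass_table(table, reference)
    cuts = calibrate_cutpoints(cumtable, target, reference)
    return cuts, cumtable


def write_cutpoints(cuts: CutPointSet, path) -> None:
    """Serialize a CutPointSet as a small key-value text file."""
    lines = ["[cutpoints]"]
    for band, k in cuts.cuts.items():
        lines.append(f"{band} = {k}")
    lines.append("[provenance]")
    lines.append(f"target = {cuts.target.lo},{cuts.target.hi}")
    lines.append(f"reference = {','.join(cuts.reference_countries)}")
    lines.append(f"fallback_bands = {','.join(cuts.fallback_bands)}")
    for band, p in cuts.achieved.items():
        lines.append(f"achieved {band} = {p!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cutpoints(path) -> CutPointSet:
    text = open(path, encoding="utf-8").read()
    cuts, achieved, reference, fallback = {}, {}, [], []
    target = TargetRange()
    section = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if section == "cutpoints":
            cuts[key] = int(val)
        elif key == "target":
            lo, hi = val.split(",")
            target = TargetRange(float(lo), float(hi))
        elif key == "reference":
            reference = [c for c in val.split(",") if c]
        elif key == "fallback_bands":
            fallback = [c for c in val.split(",") if c]
        elif key.startswith("achieved "):
            achieved[key.removeprefix("achieved ")] = float(val)
    return CutPointSet(cuts, achieved, target, reference, fallback)
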