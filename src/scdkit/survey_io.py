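"""Data model and delimited-text I/O for multi-country child survey microdata.

The unit of analysis is one child aged 24-59 months with the 11 binary
learning items (ECD5..ECD15), demographic covariates, survey design
variables (cluster, household, sampling weight) and a country code that
links to per-survey metadata (HDI, per-capita GNI, programme).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 11 learning-domain items, in instrument order.
ITEMS = [f"ECD{i}" for i in range(5, 16)]

#: Closed month intervals used for calibration and classification.
AGE_BANDS = [(24, 29), (30, 35), (36, 41), (42, 47), (48, 59)]

#: Single-year age groups used for age-trend summaries.
AGE_YEARS = {2: (24, 35), 3: (36, 47), 4: (48, 59)}

MANDATORY_COLUMNS = [
    "country_code", "cluster_id", "household_id", "child_id",
    "age_months", "sex", "child_weight", *ITEMS,
]

OPTIONAL_COLUMNS = ["maternal_education", "ece_enrolled", "wealth_quintile"]

#: Default missing sentinels for item cells (MICS-style "9 = DK").
DEFAULT_MISSING_CODES = ("", "NA", "9")

SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("none_preprimary", "primary", "secondary_plus")
ECE_LEVELS = ("yes", "no")

HDI_GROUPS = ("very_high", "high", "medium", "low")


class SchemaError(ValueError):
    """A mandatory column is absent or mistyped."""


class ValidationError(ValueError):
    """A cell violates a row-level invariant (e.g. non-positive weight)."""


def band_label(band: tuple[int, int]) -> str:
    return f"{band[0]}-{band[1]}"


def assign_age_band(age_months: int) -> tuple[int, int]:
    """Return the closed month interval containing ``age_months``.

    Ages outside the instrument's 24-59 month range raise ``ValueError``.
    """
    age = int(age_months)
    if age != age_months:
        raise ValueError(f"age_months must be integral, got {age_months!r}")
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return (lo, hi)
    raise ValueError(f"age {age} months outside the 24-59 month range")


def assign_age_year(age_months: int) -> int:
    """Map months to the single-year groups 2 (24-35), 3 (36-47), 4 (48-59)."""
    for year, (lo, hi) in AGE_YEARS.items():
        if lo <= age_months <= hi:
            return year
    raise ValueError(f"age {age_months} months outside the 24-59 month range")


def hdi_group(hdi: float) -> str:
    """Classify an HDI value into the four development groups.

    Thresholds follow the UNDP convention: very_high >= 0.800,
    high in [0.700, 0.800), medium in [0.550, 0.700), low < 0.550.
    """
    if not 0.0 < hdi < 1.0:
        raise ValueError(f"HDI must lie strictly between 0 and 1, got {hdi}")
    if hdi >= 0.800:
        return "very_high"
    if hdi >= 0.700:
        return "high"
    if hdi >= 0.550:
        return "medium"
    return "low"


@dataclass
class SurveyTable:
    """Child microdata plus per-country survey metadata.

    ``children`` holds one row per child with the canonical columns;
    ``meta`` one row per country (country_code, hdi, pcgni, ...).
    """

    children: pd.DataFrame
    meta: pd.DataFrame | None = None
    missing_report: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in MANDATORY_COLUMNS if c not in self.children.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        if self.meta is not None and len(self.children):
            known = set(self.meta["country_code"])
            orphan = set(self.children["country_code"]) - known
            if orphan:
                raise ValidationError(
                    f"children reference countries without metadata: {sorted(orphan)}"
                )

    def __len__(self) -> int:
        return len(self.children)

    def subset(self, mask) -> "SurveyTable":
        return SurveyTable(
            self.children.loc[mask].reset_index(drop=True), self.meta,
        )

    def countries(self) -> list[str]:
        return sorted(self.children["country_code"].unique())


def _coerce_items(frame: pd.DataFrame, missing_codes) -> tuple[pd.DataFrame, int]:
    """Map item cells to float 0/1 with NaN for sentinels; count conversions."""
    n_missing = 0
    codes = {str(c) for c in missing_codes}
    for col in ITEMS:
        raw = frame[col].astype("string").str.strip()
        is_missing = raw.isna() | raw.isin(codes)
        vals = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = vals.notna() & ~vals.isin([0, 1])
        vals = vals.where(~bad)
        frame[col] = vals.astype(float)
        n_missing += int((vals.isna()).sum())
    return frame, n_missing


def read_child_table(
    path,
    missing_codes=DEFAULT_MISSING_CODES,
    meta: pd.DataFrame | None = None,
) -> SurveyTable:
    """Read a UTF-8 comma-separated child table with a header row.

    Items must be coded 0/1 with cells in ``missing_codes`` treated as
    missing.  Unparseable cells become missing and are counted in the
    returned table's ``missing_report``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")

    frame, n_item_missing = _coerce_items(frame, missing_codes)

    frame["age_months"] = pd.to_numeric(frame["age_months"], errors="raise").astype(int)
    weights = pd.to_numeric(frame["child_weight"], errors="coerce")
    bad_w = weights.isna() | (weights <= 0)
    if bad_w.any():
        idx = int(np.flatnonzero(bad_w.to_numpy())[0])
        raise ValidationError(f"non-positive or unparseable child_weight at row {idx}")
    frame["child_weight"] = weights.astype(float)

    out_of_range = ~frame["age_months"].between(24, 59)
    if out_of_range.any():
        idx = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise ValidationError(f"age_months outside [24, 59] at row {idx}")

    for col, levels in [("sex", SEX_LEVELS)]:
        bad = ~frame[col].isin(levels)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"invalid {col} at row {idx}: {frame[col].iloc[idx]!r}")

    report = {"items": n_item_missing}
    for col, levels in [("maternal_education", EDUCATION_LEVELS), ("ece_enrolled", ECE_LEVELS)]:
        if col in frame.columns:
            vals = frame[col].astype("string").str.strip()
            vals = vals.where(vals.isin(levels))
            report[col] = int(vals.isna().sum())
            frame[col] = vals
        else:
            frame[col] = pd.Series(pd.NA, index=frame.index, dtype="string")

    if "wealth_quintile" in frame.columns:
        q = pd.to_numeric(frame["wealth_quintile"], errors="coerce")
        bad_q = q.notna() & ~q.isin([1, 2, 3, 4, 5])
        if bad_q.any():
            idx = int(np.flatnonzero(bad_q.to_numpy())[0])
            raise ValidationError(f"wealth_quintile outside 1..5 at row {idx}")
        frame["wealth_quintile"] = q.astype("Float64")
    else:
        frame["wealth_quintile"] = pd.Series(np.nan, index=frame.index, dtype="Float64")

    table = SurveyTable(frame.reset_index(drop=True), meta)
    table.missing_report = report
    return table


def write_child_table(table: SurveyTable, path) -> None:
    """Write the child table back to CSV; inverse of :func:`read_child_table`."""
    frame = table.children.copy()
    for col in ITEMS:
        frame[col] = frame[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    for col in ("maternal_education", "ece_enrolled"):
        frame[col] = frame[col].fillna("")
    frame["wealth_quintile"] = frame["wealth_quintile"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    frame.to_csv(path, index=False)


def read_country_meta(path) -> pd.DataFrame:
    """Read per-survey country metadata; derives hdi_group from hdi."""
    meta = pd.read_csv(path)
    for col in ("country_code", "hdi", "pcgni"):
        if col not in meta.columns:
            raise SchemaError(f"missing mandatory column(s): {col}")
    if (meta["pcgni"] <= 0).any():
        raise ValidationError("pcgni must be positive")
    meta["hdi_group"] = meta["hdi"].map(hdi_group)
    return meta


def complete_case_filter(
    table: SurveyTable, required: list[str]
) -> tuple[SurveyTable, dict]:
    """Drop rows with any missing required field (complete-case analysis).

    Returns the filtered table and a report with per-field and total drop
    fractions.  An empty result is allowed and flagged in the report.
    """
    frame = table.children
    absent = [f for f in required if f not in frame.columns]
    if absent:
        raise SchemaError(f"required field(s) not in schema: {', '.join(absent)}")
    n = len(frame)
    missing = frame[required].isna()
    drop_mask = missing.any(axis=1)
    report = {
        "n_input": n,
        "n_dropped": int(drop_mask.sum()),
        "total_drop_fraction": float(drop_mask.mean()) if n else 0.0,
        "per_field": {f: (float(missing[f].mean()) if n else 0.0) for f in required},
        "empty_result": bool(n and drop_mask.all()),
    }
    return table.subset(~drop_mask), report


def survey_table_to_csv(table: SurveyTable) -> str:
    buf = io.StringIO()
    write_child_table(table, buf)
    return buf.getvalue()
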