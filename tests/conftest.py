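import numpy as np
import pandas as pd
import pytest

from scdkit.survey_io import ITEMS, SurveyTable
from scdkit.synthetic_data import SimConfig, simulate_reference_pool, simulate_survey


def make_children(rows: list[dict]) -> pd.DataFrame:
    """Tiny child table with sensible defaults for unspecified fields."""
    out = []
    for i, row in enumerate(rows):
        rec = {
            "country_code": "AA", "cluster_id": "AA-K1",
            "household_id": f"AA-H{i}", "child_id": f"AA-B{i}",
            "age_months": 40, "sex": "female",
            "maternal_education": "primary", "ece_enrolled": "no",
            "wealth_quintile": 3, "child_weight": 1.0,
            **{it: 1.0 for it in ITEMS},
        }
        rec.update(row)
        out.append(rec)
    frame = pd.DataFrame(out)
    frame["wealth_quintile"] = frame["wealth_quintile"].astype("Float64")
    return frame


@pytest.fixture
def tiny_table() -> SurveyTable:
    return SurveyTable(make_children([{} for _ in range(10)]))


@pytest.fixture(scope="session")
def default_survey() -> SurveyTable:
    """One moderate multi-country survey shared across tests."""
    return simulate_survey(SimConfig(seed=1))


@pytest.fixture(scope="session")
def reference_pool() -> SurveyTable:
    """The high-development calibration pool (about 20k children)."""
    return simulate_reference_pool(SimConfig(seed=1))
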