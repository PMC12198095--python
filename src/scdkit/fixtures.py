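"""Published summary tables packaged as fixtures.

Three small tables from the source study travel with the package so the
desk-scale analyses (reliability summary, cut-point calibration, pooled
prevalence ratios, measure comparison) can be recomputed without access
to the licensed microdata:

* ``table2_countries`` — 23 surveys: HDI 2021, per-capita GNI 2021 (USD,
  Atlas method), sample size, McDonald's omega for the 11 learning items,
  SCD prevalence from the new 11-item instrument (with 95% CI) and, where
  previously published, SCD prevalence from the legacy 10-item instrument.
* ``table3_cumulative`` — pooled weighted cumulative pass rates (percent
  of children passing <= k items, k = 0..5) in the nine reference
  countries, by age band; cells printed only as ">10%" are censored.
* ``table5_pooled`` — pooled SCD prevalence (percent) among 3-4-year-olds
  by HDI group and early-childhood-education enrolment.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .survey_io import AGE_BANDS, band_label, hdi_group

_TABLE2_CSV = """\
country,survey_year,hdi,programme,pcgni,sample_size,response_rate,omega,prevalence_ecdi2030,prev2030_ci_low,prev2030_ci_high,prevalence_ecdi,prev_ecdi_ci_low,prev_ecdi_ci_high
Trinidad and Tobago,2022,0.810,MICS,14850,1141,87.7,0.831,2.2,1.2,4.2,0.6,0.2,1.7
Thailand,2022,0.800,MICS,7090,6962,93.5,0.841,4.2,3.2,5.6,0.4,0.2,0.6
Azerbaijan,2023,0.738,MICS,4910,1596,92.5,0.736,4.5,3.3,6.0,,,
Jordan,2023,0.736,DHS,4210,3304,96.9,0.837,4.9,3.7,6.5,,,
Tunisia,2023,0.731,MICS,3560,1245,95.0,0.846,4.0,2.9,5.4,4.1,3.2,5.2
Fiji,2021,0.730,MICS,4500,1074,97.5,0.832,5.1,3.8,6.8,,,
Uzbekistan,2021/22,0.727,MICS,1980,1159,99.3,0.829,4.0,2.9,5.5,,,
Jamaica,2022,0.709,MICS,5190,830,92.8,0.832,1.0,0.5,1.8,0.5,0.2,1.4
Viet Nam,2020/21,0.703,MICS,3590,2535,97.2,0.804,4.3,3.3,5.5,3.0,2.1,4.3
Philippines,2022,0.699,DHS,3550,4561,98.0,0.812,5.8,4.9,6.9,,,
Kyrgyzstan,2023,0.696,MICS,1280,1857,97.6,0.777,7.9,6.5,9.6,5.5,4.4,6.8
Nauru,2023,0.693,MICS,18010,201,81.3,0.862,8.8,5.4,14.1,,,
Lao PDR,2023,0.607,MICS,2500,5155,98.7,0.806,12.0,10.9,13.3,2.3,1.9,2.8
Vanuatu,2023,0.607,MICS,3350,1256,93.8,0.839,7.7,5.9,10.0,,,
Eswatini,2021/22,0.597,MICS,3740,1322,93.1,0.763,10.6,8.7,12.9,3.8,2.7,5.1
Kenya,2022,0.575,DHS,2080,5423,94.8,0.840,5.5,4.8,6.3,,,
Comoros,2022,0.558,MICS,1580,1767,95.3,0.839,27.9,24.6,31.4,,,
Cote d'Ivoire,2021,0.550,DHS,2470,5480,98.1,0.770,27.0,25.1,28.9,10.7,7.4,15.1
Tanzania,2022,0.549,DHS,1120,5529,96.9,0.808,25.5,23.6,27.4,,,
Nigeria,2020/21,0.535,MICS,2120,16459,97.9,0.820,17.3,16.3,18.3,15.8,14.6,18.3
Benin,2021/22,0.525,MICS,1330,7796,98.4,0.810,28.2,26.4,30.0,19.6,17.5,21.8
Afghanistan,2022/23,0.478,MICS,390,13500,98.8,0.725,19.1,18.0,20.2,,,
Mozambique,2022/23,0.473,DHS,490,2277,94.3,0.821,34.1,30.9,37.4,,,
"""

# Pooled cumulative pass rates (%) for k = 0..5 items passed in the nine
# high / very-high HDI reference countries; NaN marks cells published only
# as ">10%" (censored, never selectable as a cut-point).
_TABLE3_ROWS = {
    (24, 29): [5.3, None, None, None, None, None],
    (30, 35): [4.2, 8.8, None, None, None, None],
    (36, 41): [0.9, 2.0, 4.7, 8.1, None, None],
    (42, 47): [0.6, 1.6, 3.4, 6.2, None, None],
    (48, 59): [0.4, 0.9, 1.4, 2.2, 3.6, 7.3],
}

_TABLE5_CSV = """\
enrolment,very_high,high,medium,low
enrolled,2.3,2.5,7.6,12.2
not_enrolled,6.3,5.8,17.7,23.7
total,3.3,4.2,15.7,23.2
"""


def table2_countries() -> pd.DataFrame:
    """The 23-survey country table with derived hdi_group labels."""
    frame = pd.read_csv(io.StringIO(_TABLE2_CSV))
    frame["hdi_group"] = frame["hdi"].map(hdi_group)
    return frame


def table3_cumulative() -> pd.DataFrame:
    """Censored cumulative pass-rate table: bands x k, percent, NaN = ">10%"."""
    data = {band_label(b): _TABLE3_ROWS[b] for b in AGE_BANDS}
    frame = pd.DataFrame(data, index=pd.RangeIndex(6, name="items_passed")).T
    frame.index.name = "age_band"
    return frame.astype(float)


def table5_pooled() -> pd.DataFrame:
    """Pooled SCD prevalence (%) by HDI group x ECE enrolment."""
    return pd.read_csv(io.StringIO(_TABLE5_CSV), index_col="enrolment")


def comparison_pairs() -> pd.DataFrame:
    """Countries with SCD prevalence printed for both instrument versions."""
    t2 = table2_countries()
    both = t2.dropna(subset=["prevalence_ecdi"])
    return both[["country", "prevalence_ecdi2030", "prevalence_ecdi"]].reset_index(drop=True)


def make_fixtures(out_dir) -> dict[str, Path]:
    """Write the packaged tables as CSV files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame, kw in [
        ("table2_countries", table2_countries(), dict(index=False)),
        ("table3_cumulative", table3_cumulative(), dict()),
        ("table5_pooled", table5_pooled(), dict()),
    ]:
        path = out / f"{name}.csv"
        frame.to_csv(path, **kw)
        paths[name] = path
    return paths
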