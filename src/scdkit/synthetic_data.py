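"""Synthetic multi-country, cluster-sampled child survey generator.

Real MICS/DHS microdata are licensed, so every downstream stage is
exercised on simulated surveys with the same statistical structure:
children nested in clusters nested in countries, 11 binary learning items
whose pass probability rises with age and latent ability, a development
gradient across countries, covariate effects (sex, household wealth,
maternal education, early-childhood-education enrolment), log-normal
sampling weights and small completely-at-random missingness.

The generative model is a one-factor item-response model: child ability

    theta = intercept + age_slope*(age - 24) + country_hdi_effect*(hdi - mid)
            + wealth_effect*wealth_z + edu + ece + male + cluster + noise

and item j is passed with probability logistic(a * (theta - delta_j)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survey_io import ITEMS, SurveyTable
from .wealth_index import assign_quintiles

#: Default item difficulties on the latent scale, in instrument order
#: ECD5..ECD15.  Early language milestones ("say 10 or more words") are
#: easiest; pre-literacy/numeracy milestones ("write name") are hardest.
#: Difficulties are evenly spaced (gap 0.2) along the milestone-hardness
#: ranking so the summed score's lower tail moves smoothly through the
#: calibration zone in every age band; the default age slope advances
#: ability by exactly one difficulty gap per six months of age.
_MILESTONE_RANKS = (1, 3, 5, 4, 2, 10, 11, 9, 6, 8, 7)  # ECD5..ECD15
DIFFICULTY_GAP = 0.2
DEFAULT_DIFFICULTIES = tuple(-2.4 + DIFFICULTY_GAP * (r - 1) for r in _MILESTONE_RANKS)

EDU_LEVELS = ("none_preprimary", "primary", "secondary_plus")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic survey; defaults are the study conditions.

    Effects are on the latent ability scale (logistic link with
    discrimination ``discrimination``).  ``missing_rates`` holds the
    completely-at-random missingness fractions for (items, maternal
    education, ECE enrolment); the defaults are the observed real-data
    fractions 3.0%, 0.6% and 0.1%.
    """

    n_countries: int = 20
    hdi_range: tuple[float, float] = (0.45, 0.85)
    clusters_per_country: int = 30
    children_per_cluster: int = 25
    item_difficulties: tuple = DEFAULT_DIFFICULTIES
    discrimination: float = 6.0
    intercept: float = 0.5
    age_slope: float = DIFFICULTY_GAP / 6.0
    country_hdi_effect: float = 3.0
    wealth_effect: float = 0.25
    edu_effects: tuple = (-0.5, -0.25, 0.0)  # none/pre-primary, primary, secondary+
    ece_effect: float = 0.3
    male_effect: float = -0.1
    cluster_sd: float = 0.3
    residual_sd: float = 1.6
    weight_cv: float = 0.5
    missing_rates: tuple = (0.03, 0.006, 0.001)
    age_range: tuple[int, int] = (24, 59)
    seed: int = 0

    def __post_init__(self):
        if self.n_countries < 1 or self.clusters_per_country < 1 or self.children_per_cluster < 1:
            raise ValueError("n_countries, clusters and children per cluster must be >= 1")
        if len(self.item_difficulties) != len(ITEMS):
            raise ValueError(f"need {len(ITEMS)} item difficulties")
        if not all(0.0 <= r <= 1.0 for r in self.missing_rates):
            raise ValueError("missing rates must lie in [0, 1]")
        if min(self.cluster_sd, self.residual_sd, self.weight_cv) < 0:
            raise ValueError("standard deviations must be non-negative")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _country_hdis(config: SimConfig) -> np.ndarray:
    """Evenly spaced HDI values across the configured range (deterministic)."""
    lo, hi = config.hdi_range
    if config.n_countries == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, config.n_countries)


def _education_probs(hdi: float) -> np.ndarray:
    """Maternal-education mix shifts toward secondary+ as HDI rises."""
    p_sec = float(np.clip(1.4 * hdi - 0.35, 0.05, 0.9))
    p_prim = 0.6 * (1.0 - p_sec)
    return np.array([1.0 - p_sec - p_prim, p_prim, p_sec])


def simulate_survey(config: SimConfig) -> SurveyTable:
    """Generate a complete multi-country survey, reproducible from the seed.

    Draws use a single pseudo-random stream in a fixed order (per country:
    cluster effects, then child ages, sex, household wealth, maternal
    education, ECE enrolment, residual ability, items, weights,
    missingness), so identical configs yield identical tables.
    """
    rng = np.random.default_rng(config.seed)
    hdis = _country_hdis(config)
    hdi_mid = float(np.mean(config.hdi_range))
    delta = np.asarray(config.item_difficulties, dtype=float)
    a = config.discrimination
    age_lo, age_hi = config.age_range

    frames = []
    meta_rows = []
    for i, hdi in enumerate(hdis):
        code = f"C{i + 1:02d}"
        n_cl = config.clusters_per_country
        n_ch = n_cl * config.children_per_cluster

        cluster_eff = rng.normal(0.0, config.cluster_sd, n_cl)
        cluster_idx = np.repeat(np.arange(n_cl), config.children_per_cluster)

        age = rng.integers(age_lo, age_hi + 1, n_ch)
        male = rng.integers(0, 2, n_ch).astype(bool)
        wealth_z = rng.normal(0.0, 1.0, n_ch)
        edu_idx = rng.choice(3, size=n_ch, p=_education_probs(hdi))
        ece_p = float(np.clip(0.15 + 0.9 * (hdi - 0.45), 0.05, 0.9))
        ece_yes = rng.random(n_ch) < ece_p
        resid = rng.normal(0.0, config.residual_sd, n_ch)

        theta = (
            config.intercept
            + config.age_slope * (age - 24)
            + config.country_hdi_effect * (hdi - hdi_mid)
            + config.wealth_effect * wealth_z
            + np.asarray(config.edu_effects)[edu_idx]
            + config.ece_effect * (ece_yes & (age >= 36))
            + config.male_effect * male
            + cluster_eff[cluster_idx]
            + resid
        )
        items = (rng.random((n_ch, len(ITEMS))) < _expit(a * (theta[:, None] - delta))).astype(float)

        if config.weight_cv > 0:
            sigma2 = np.log1p(config.weight_cv ** 2)
            weights = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n_ch)
        else:
            weights = np.ones(n_ch)

        # MCAR missingness: items cell-wise, then covariates
        r_items, r_edu, r_ece = config.missing_rates
        if r_items > 0:
            items[rng.random(items.shape) < r_items] = np.nan
        edu = pd.array([EDU_LEVELS[k] for k in edu_idx], dtype="string")
        if r_edu > 0:
            edu[rng.random(n_ch) < r_edu] = pd.NA
        ece = pd.array(np.where(ece_yes, "yes", "no"), dtype="string")
        ece[age < 36] = pd.NA  # structurally missing below 36 months
        if r_ece > 0:
            ece[(rng.random(n_ch) < r_ece) & (age >= 36)] = pd.NA

        quintile = assign_quintiles(wealth_z, weights)

        frame = pd.DataFrame({
            "country_code": code,
            "cluster_id": [f"{code}-K{k + 1:03d}" for k in cluster_idx],
            "household_id": [f"{code}-H{j + 1:05d}" for j in range(n_ch)],
            "child_id": [f"{code}-B{j + 1:05d}" for j in range(n_ch)],
            "age_months": age,
            "sex": np.where(male, "male", "female"),
            "maternal_education": edu,
            "ece_enrolled": ece,
            "wealth_quintile": pd.array(quintile, dtype="Float64"),
            "child_weight": weights,
        })
        for j, name in enumerate(ITEMS):
            frame[name] = items[:, j]
        frames.append(frame)

        meta_rows.append({
            "country_code": code,
            "survey_year": "2022",
            "programme": "MICS" if i % 3 else "DHS",
            "hdi": float(hdi),
            "pcgni": float(np.round(np.exp(0.8 + 10.8 * hdi), -1)),
            "age_coverage": f"{age_lo}-{age_hi}",
        })

    children = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(meta_rows)
    from .survey_io import hdi_group
    meta["hdi_group"] = meta["hdi"].map(hdi_group)
    return SurveyTable(children, meta)


#: Reference-pool conditions: the nine high / very-high development
#: countries used to calibrate cut-points, ~20,000 children in total, with
#: the same ability model as the full simulation.  Under these defaults
#: each age band's lower score tail passes through the 3-5% target zone.
REFERENCE_OVERRIDES = dict(
    n_countries=9,
    hdi_range=(0.70, 0.85),
    clusters_per_country=30,
    children_per_cluster=75,
)


def simulate_reference_pool(config: SimConfig | None = None,
                            target: tuple[float, float] = (3.0, 5.0)) -> SurveyTable:
    """Simulate the high-development reference pool used for calibration.

    ``target`` is the intended calibration range in percent; it is recorded
    for provenance only — the pool itself is generated so that a cumulative
    score proportion near that range exists in every age band.
    """
    base = config if config is not None else SimConfig()
    pool_cfg = replace(base, **REFERENCE_OVERRIDES)
    table = simulate_survey(pool_cfg)
    table.missing_report["calibration_target"] = tuple(target)
    return table
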