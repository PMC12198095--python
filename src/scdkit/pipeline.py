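"""End-to-end orchestration of the four analysis stages.

``run_pipeline`` executes, in order: (1) reliability of the 11 learning
items per country, (2) cut-point calibration on the high-development
reference pool, (3) survey-weighted prevalence, age trends and the
Poisson risk models, (4) the old-vs-new measure comparison (computed on
the packaged published prevalence pairs, since no legacy scores exist for
synthetic children).  Outputs are delimited tables plus a run manifest;
everything is deterministic given the seed.

The numbered scripts under ``analysis/`` are thin drivers over this
module and the underlying stage modules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .country_level import compare_measures, comparison_text, spearman_ci
from .estimation import (pooled_prevalence, prevalence_by_age,
                         prevalence_by_country, prevalence_ratio)
from .fixtures import comparison_pairs, make_fixtures  # noqa: F401  (re-export)
from .multilevel import RegressionSpec, regression_table
from .reliability import omega_by_country, summarize_omegas
from .scd_scoring import TargetRange, calibrate_from_survey, flag_scd, write_cutpoints
from .survey_io import SurveyTable, read_child_table, read_country_meta
from .synthetic_data import SimConfig, simulate_survey

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of (children_path, meta_path) or ``sim`` must be given."""
    children_path: str | None = None
    meta_path: str | None = None
    sim: SimConfig | None = None
    target: TargetRange = field(default_factory=TargetRange)
    reference_countries: list[str] | None = None
    regression: RegressionSpec = field(default_factory=RegressionSpec)
    min_stratum_n: int = 100
    out_dir: str = "results/pipeline"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        has_files = self.children_path is not None
        if has_files == (self.sim is not None):
            raise ValueError("provide exactly one of input paths or a SimConfig")
        if has_files and self.meta_path is None:
            raise ValueError("children_path requires meta_path")


def _load(config: PipelineConfig) -> SurveyTable:
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        return simulate_survey(sim)
    meta = read_country_meta(config.meta_path)
    return read_child_table(config.children_path, meta=meta)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all four stages; returns the result bundle and writes reports."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    table = _load(config)
    logger.info("stage 0: loaded %d children in %d countries",
                len(table), len(table.countries()))

    # stage 1 — reliability
    try:
        omegas = omega_by_country(table, min_n=config.min_stratum_n)
        omega_frame = pd.DataFrame([
            {"country_code": c, "n": r.n_used, "omega": r.omega,
             "converged": r.converged, "heywood_flag": r.heywood}
            for c, r in sorted(omegas.items())
        ])
        omega_frame.to_csv(out / "omega_by_country.csv", index=False)
        summary = summarize_omegas(omega_frame["omega"], omega_frame["country_code"])
        bundle["omega"] = {"per_country": omega_frame, "summary": summary}
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 1 (reliability) failed: {exc}") from exc

    # stage 2 — calibration
    try:
        cuts, cumtable = calibrate_from_survey(
            table, config.target, config.reference_countries)
        cumtable.to_csv(out / "cumulative_pass_rates.csv")
        write_cutpoints(cuts, out / "cutpoints.txt")
        bundle["cuts"], bundle["cumtable"] = cuts, cumtable
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 2 (calibration) failed: {exc}") from exc

    # stage 3 — prevalence + risk models
    try:
        prev = prevalence_by_country(table, cuts)
        prev.to_csv(out / "prevalence_by_country.csv", index=False)
        grouping = dict(zip(table.meta["country_code"], table.meta["hdi_group"]))
        pooled = pooled_prevalence(table, grouping, cuts=cuts)
        pooled_frame = pd.DataFrame([
            {"group": g, "prevalence": e.p_hat, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "n": e.n}
            for g, e in pooled.items()
        ])
        pooled_frame.to_csv(out / "pooled_prevalence.csv", index=False)
        ages = prevalence_by_age(table, cuts)
        ages["per_country"].to_csv(out / "prevalence_by_age.csv")
        merged = prev.merge(table.meta, on="country_code")
        bundle["spearman_hdi"] = spearman_ci(merged["prevalence"], merged["hdi"])
        bundle["spearman_pcgni"] = spearman_ci(merged["prevalence"], merged["pcgni"])
        reg = regression_table(_with_scd(table, cuts), config.regression)
        reg.to_csv(out / "regression_table.csv", index=False)
        bundle.update(prevalence=prev, pooled=pooled, ages=ages, regression=reg)
        _age_trend_plot(ages["per_country"], table.meta, out / "prevalence_by_age.png")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 3 (estimation/modelling) failed: {exc}") from exc

    # stage 4 — measure comparison on the published prevalence pairs
    try:
        pairs = comparison_pairs()
        report = compare_measures(pairs["prevalence_ecdi2030"], pairs["prevalence_ecdi"])
        (out / "comparison.txt").write_text(comparison_text(report) + "\n",
                                            encoding="utf-8")
        bundle["comparison"] = report
        if len(pooled) >= 2 and "very_high" in pooled and "low" in pooled:
            bundle["low_vs_very_high"] = prevalence_ratio(
                pooled["low"], pooled["very_high"])
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 4 (comparison) failed: {exc}") from exc

    _write_manifest(config, out)
    return bundle


def _with_scd(table: SurveyTable, cuts) -> SurveyTable:
    frame = table.children.copy()
    frame["scd"] = flag_scd(table, cuts)
    return SurveyTable(frame, table.meta)


def _age_trend_plot(per_country: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Mean SCD prevalence by age for the upper and lower HDI halves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = meta.sort_values("hdi", ascending=False)["country_code"].tolist()
    half = len(ranked) // 2
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, codes in [("higher HDI", ranked[:half]), ("lower HDI", ranked[half:])]:
        sub = per_country.loc[per_country.index.intersection(codes)]
        means = sub.mean()
        sems = sub.std(ddof=1) / np.sqrt(sub.notna().sum())
        ax.errorbar(means.index, means, yerr=1.96 * sems, marker="o",
                    capsize=3, label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("SCD prevalence (%)")
    ax.set_xticks([2, 3, 4])
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    cfg_repr = repr(config)
    manifest = {
        "seed": config.seed,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": cfg_repr,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                       encoding="utf-8")
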