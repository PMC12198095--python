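# scdkit

Tools for deriving an indicator of **Significant Cognitive Delay (SCD)** in
2–4-year-old children from the 11 binary learning items (ECD5–ECD15) of
UNICEF's ECDI2030 instrument, as collected in multi-country household
surveys (MICS and DHS).

Intellectual-disability research is dominated by high-income countries.
Survey programmes in low- and middle-income countries already collect
caregiver-reported developmental milestones on nationally representative
samples of young children; `scdkit` implements the full analysis chain that
turns those items into a screening-style prevalence indicator:

1. **Reliability** — McDonald's omega for the 11-item learning scale,
   overall, per country and per stratum, where
   ω = (Σλ)² / ((Σλ)² + Σθ) from a one-factor minimum-residual fit
   of the weighted item correlation matrix.
2. **Calibration** — the summed learning score s ∈ {0,…,11} is tabulated as
   weighted cumulative pass rates P(s ≤ k) per age band (24–29, 30–35,
   36–41, 42–47, 48–59 months) in a pool of reference countries with high
   or very-high Human Development Index; the cut-point k\*(band) is the
   largest k whose proportion falls in a 3–5 % target range (the share of
   children expected to show significant delay in well-off settings).
   A child is classified SCD when s ≤ k\* for their band.
3. **Estimation** — survey-weighted prevalence p̂ = Σwᵢfᵢ / Σwᵢ with
   logit-scale Wald intervals using the Kish effective sample size
   (Σw)²/Σw²; pooled group estimates, prevalence ratios and age trends.
4. **Risk modelling** — Poisson regression of the 0/1 SCD flag (log link, no
   offset), so exp(β) is a prevalence rate ratio: bivariate mixed-effects
   models with country-level random intercept and slope integrated by
   mean–variance adaptive Gauss–Hermite quadrature, and a multivariate
   fixed-effects model with country indicators.
5. **Country-level comparison** — Spearman correlations of national
   prevalence with HDI and per-capita GNI (Fisher-z intervals), and a
   paired comparison of prevalences from the new 11-item scoring against
   the legacy 10-item ECDI-based measure.

Real MICS/DHS microdata are licensed, so the package ships a synthetic
multi-country survey generator (`scdkit.synthetic_data`) with the same
statistical structure — children in clusters in countries, an item-response
ability model, development gradients, covariate effects, sampling weights
and realistic missingness — plus the small published summary tables
(`scdkit.fixtures`) needed to reproduce the desk-scale results.

## Worked example

```python
from scdkit import (SimConfig, simulate_survey, simulate_reference_pool,
                    calibrate_from_survey, pooled_prevalence)

survey = simulate_survey(SimConfig(seed=1))          # 20 countries, 15,000 children
pool   = simulate_reference_pool(SimConfig(seed=1))  # 9 high-HDI countries, 20,250 children

cuts, cumtable = calibrate_from_survey(pool)
print(cuts.cuts)
# {'24-29': 0, '30-35': 1, '36-41': 2, '42-47': 4, '48-59': 5}
print({b: round(p, 2) for b, p in cuts.achieved.items()})
# {'24-29': 3.82, '30-35': 3.85, '36-41': 4.26, '42-47': 4.97, '48-59': 4.45}

grouping = dict(zip(survey.meta["country_code"], survey.meta["hdi_group"]))
pooled = pooled_prevalence(survey, grouping, cuts=cuts)
print({g: round(e.p_hat, 1) for g, e in pooled.items()})
# {'high': 3.0, 'low': 8.8, 'medium': 5.7, 'very_high': 1.6}
```

Each band's cut-point flags 3.8–5.0 % of reference-pool children, and
applying those cut-points to the full simulated survey recovers the
configured development gradient: SCD prevalence rises monotonically from
1.6 % in very-high-HDI countries to 8.8 % in low-HDI countries.

The numbered scripts under `analysis/` run the same stages as narrative
drivers — `01_published_tables.py` (published-table analyses),
`02_simulate_survey.py`, `03_calibrate_and_prevalence.py`,
`04_risk_models.py`, `05_full_pipeline.py` — writing their tables under
`results/`.

## Layout

```
src/scdkit/        survey_io, synthetic_data, wealth_index, reliability,
                   scd_scoring, estimation, multilevel, country_level,
                   fixtures, pipeline
analysis/          numbered narrative drivers over the package
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model, assumptions, numerical choices, limitations
```
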