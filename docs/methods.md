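# Methods

## The indicator

A child aged 24–59 months answers (by caregiver report) 11 binary learning
items. The summed score s counts items passed. Within five age bands
(24–29, 30–35, 36–41, 42–47, 48–59 months), weighted cumulative pass rates
P(s ≤ k) are tabulated in a pool of reference countries with high or
very-high Human Development Index (HDI ≥ 0.700). The cut-point k\*(band) is
the largest k whose cumulative proportion, rounded to one decimal of a
percent, lies in a 3–5 % target range; a child is classified as having
Significant Cognitive Delay (SCD) when s ≤ k\*. The 3–5 % target reflects
the share of children expected to have significant delay in
well-off settings, adjusted upward because most reference countries here
are "high" rather than "very high" development.

When no k lands in the target range the band is resolved by a
nearest-to-interval fallback (distance to the closer endpoint, smaller k on
ties, censored cells never selectable). On the published pooled table this
fallback is exercised exactly once — the youngest band's smallest
proportion is 5.3 % — and reproduces the published thresholds
0, 0, 2, 2, 4. The fallback is this package's explicit resolution of an
ambiguity in how that 5.3 % value was accepted as "approximately 3–5 %".

HDI groups follow the UNDP convention: very high ≥ 0.800,
high [0.700, 0.800), medium [0.550, 0.700), low < 0.550. Age bands are
closed integer-month intervals; 59 months is the oldest accepted age.

## Reliability

McDonald's omega is computed from a one-factor decomposition of the
weighted **Pearson** correlation matrix of the raw binary items, fitted by
minimum-residual (off-diagonal least squares) with analytic gradient;
negative uniquenesses are truncated at 1e−6 and flagged (Heywood).
Omega = (Σλ)²/((Σλ)² + Σθ) on the standardized solution. A tetrachoric
input matrix would give higher loadings for binary items; the Pearson
choice matches common general-purpose omega implementations and keeps the
estimator fast. Survey weights enter the correlation matrix; both choices
are surfaced in the API. The cross-country summary uses an arithmetic mean
with a t-based 95 % CI over country-level omegas.

## Prevalence estimation

Weighted prevalence p̂ = Σwf/Σw with a Wald interval on the logit scale and
the Kish effective sample size n_eff = (Σw)²/Σw² in place of a
design-based variance. This yields the asymmetric intervals typical of
survey reports, is invariant to rescaling weights, and equals the
unweighted estimator under equal weights. It ignores cluster-level
correlation; a full Taylor-linearised cluster variance is deliberately out
of scope. Degenerate samples (0 % or 100 %) get a one-sided interval via a
half-count continuity correction and a flag. Group means over countries
are unweighted (each country is one observation); prevalence ratios are
reported to one decimal. Age years map as 2 = 24–35, 3 = 36–47,
4 = 48–59 months.

## Mixed- and fixed-effects Poisson models

The binary SCD flag is modelled as a 0/1 count with log link and no offset,
so exponentiated coefficients are prevalence rate ratios (PRR). Reference
levels: female; richest wealth quintile; secondary-or-higher maternal
education; enrolled in early childhood education. Regressions are
restricted to 36–59-month-olds, the range for which the enrolment item is
defined. Sampling weights do not enter the regressions (they are used for
prevalence only); a weighted pseudo-likelihood variant exists behind a flag
on the low-level fitter.

*Bivariate mode* fits one exposure with a country-level random intercept
and, when the exposure enters as a single column, an independent random
slope (diagonal covariance, log-standard-deviation parametrisation).
Multi-level exposures keep a random intercept only, bounding the quadrature
dimension at two. *Multivariate mode* fits all exposures jointly with
country indicator variables (fixed effects); countries with no outcome
variation are dropped with a flag, since their indicators diverge.

The marginal likelihood integrates the random effects per country by
**mean–variance adaptive Gauss–Hermite quadrature** (default 7 nodes per
dimension): each country's integrand is recentred at its empirical-Bayes
mode (found by damped Newton on the strictly concave conditional
log-posterior) and rescaled by the Cholesky factor of the inverse
curvature. Observations are first collapsed to (group × covariate-pattern)
sufficient cells, which makes the likelihood cost independent of sample
size for categorical designs. Optimisation is quasi-Newton (L-BFGS-B) to a
projected-gradient tolerance of 1e−6 with the random-effect standard
deviations bounded in [1e−6, 50]; the linear predictor is capped at 30 to
keep the objective finite far from the optimum. Verified properties: at
zero variance the marginal likelihood equals the conditional Poisson
likelihood exactly and the MLE matches an ordinary Poisson GLM; at 15
nodes the one-dimensional likelihood matches dense-grid integration to
better than 1e−6.

Standard errors come from the numerically differentiated observed
information. When a variance component is estimated at (or squeezed
against) the zero boundary the full information matrix is singular;
inference then conditions on the pinned component, using the active-block
inverse, and the fit is flagged.

**Small-sample inference.** Wald intervals for the mixed-model coefficients
use t(G−1) critical values, where G is the number of countries, rather
than normal quantiles: when a coefficient's uncertainty is dominated by a
between-country variance component estimated from G ≈ 20 countries, the
normal reference is anti-conservative. (Stata's `mepoisson` reports
z-based intervals; the deviation is deliberate.) In a null simulation
(20 countries × 2,000 children, random intercept sd 0.4 and slope sd 0.3
on the log scale, 500 replicates) the resulting 95 % interval for a null
PRR covers 1 at close to nominal rate.

**Known limitation — boundary regimes.** When the true slope heterogeneity
is small relative to its sampling uncertainty (sd ≲ 0.2 at this design),
the ML variance estimate pins at zero in a nontrivial fraction of
replicates and intervals conditioned on the boundary undercover
(~90–93 % observed). This is a generic property of ML mixed-model
inference at variance boundaries, not specific to this implementation; the
package flags pinned fits so users can fall back to the fixed-effects
model. The null-coverage bench therefore uses heterogeneity magnitudes at
which both components are identifiable.

## Country-level analyses

Spearman's rho uses average ranks for ties; Pearson's r is the ordinary
product-moment estimate. Both CIs use the Fisher z transform with standard
error 1/√(n−3) (no 1.03 small-sample correction for the Spearman case).
The instrument comparison bundles Pearson r, the two column means and a
paired t test on the country-level prevalence pairs; all p-values are
two-sided.

Applied to the packaged 23-country table, the Spearman correlation of SCD
prevalence with HDI computes to −0.89 from the rounded printed values
(more negative than the −0.78 obtainable only from unrounded estimates);
with per-capita GNI it computes to −0.67. These correlations are treated
as qualitative (strongly negative) checks. Likewise the paired t on the 11
rounded prevalence pairs computes to 3.115 where 3.12 was obtained from
unrounded data.

## Wealth index

Within each country, household asset indicators are standardised with
household weights and the first principal component (eigenvector of the
weighted correlation matrix) is the wealth score, oriented so that owning
more assets raises the score. Weighted quintiles use the midpoint
convention: a household's label is the quintile containing its weighted
CDF value at the cumulative weight below its score plus half the weight
tied at its score, so heavy households straddling a boundary get a unique
label and tied scores share one. Assignment is invariant to positive
affine transforms of scores and to rescaling weights. The exact
standardisation and tie policies used by the survey programmes are not
public; these are explicit substitutes.

## Synthetic data generator

One latent-ability item-response model generates every synthetic survey:

    theta = intercept + age_slope·(age−24) + country_hdi_effect·(hdi − mid)
            + wealth_effect·wealth_z + edu + ece + male + cluster + residual
    P(pass item j) = logistic(discrimination · (theta − delta_j))

Countries take evenly spaced HDI values across the configured range;
children sit in equally sized clusters with Gaussian cluster effects;
weights are log-normal with mean 1 and configurable coefficient of
variation (default 0.5); missingness is completely at random at the
observed real-data rates (3.0 % item cells, 0.6 % maternal education,
0.1 % enrolment). Enrolment is structurally missing below 36 months. All
draws come from one seeded stream in a fixed order, so outputs are
byte-reproducible.

Default latent parameters: item difficulties evenly spaced (gap 0.2)
along the milestone-hardness ranking (saying 10 words easiest, writing
one's name hardest); discrimination 6.0; residual ability sd 1.6; cluster
sd 0.3; age slope 0.2/6 per month (one difficulty gap per six months);
intercept 0.5; HDI effect 3.0 per HDI unit; wealth effect 0.25 per SD;
education effects −0.5/−0.25/0; enrolment 0.3; male −0.1. The gap,
discrimination and dispersion were chosen together so that the summed
score's lower tail moves through the 3–5 % calibration zone in small steps
in every age band: with soft items (discrimination near 1) the bottom of
the score distribution jumps by a factor of about two between adjacent
scores and a 2-point target window cannot reliably contain a rung, whereas
sharp items tie the score tail to the smooth latent-ability tail. The
reference pool (`simulate_reference_pool`) applies this model to nine
countries with HDI 0.70–0.85, ~20,250 children, matching the scale of the
real calibration pool.

What the generator does **not** emulate: real item response curves
(caregiver-reported milestones are far noisier — discrimination 6 gives
synthetic omegas near 0.95 versus ~0.81 observed in real surveys);
informative missingness; unequal cluster sizes and design strata;
within-household correlation beyond the cluster effect; any particular
country's distributions. Passing tests on synthetic data therefore
demonstrate the correctness of the estimators and the calibration
machinery under the assumed model, not the field behaviour of the
indicator.

## Numerical conventions

Proportions are rounded to one decimal of a percent before the calibration
in-range test (matching how the pooled table is printed); reported
percentages use one decimal and correlations two. Missing item sentinels
in delimited files default to {"", "NA", "9"} ("9 = don't know" coding).
Weights are used as supplied — no renormalisation — and every estimator is
scale-invariant in them. Complete-case analysis throughout, mirroring the
small missingness fractions; the filter reports per-field and total drop
fractions.

## Problem sizes used in the benches

The default synthetic survey is 20 countries × 30 clusters × 25 children
(15,000); the reference pool 9 × 30 × 75 (20,250); the null-coverage bench
500 replicates of 20 countries × 2,000 children; omega recovery uses
100,000 draws. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances.
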