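# Methods

## Model

Adult BMI within a (sex, birth-cohort, survey-year) cell is treated as
lognormal: `log(BMI) ~ Normal(mu, sigma)`. This is an empirical choice:
among the two-parameter families suggested by the squared-skewness /
kurtosis diagnostic (lognormal, gamma, Weibull), the lognormal attains the
smallest Kolmogorov–Smirnov statistic on BMI-like data, and the package's
`cohort.compare_distributions` reproduces that comparison (all three fitted
by maximum likelihood with location fixed at 0, KS evaluated at the fitted
parameters, no small-sample correction).

Cell parameters are the closed-form MLEs: `mu_hat` = mean of log BMI,
`sigma_hat` = population standard deviation (divisor n) of log BMI. Cells
are sex-specific because sex enters the trend regressions as a covariate of
the cell-level parameters; cohorts are calendar decades (birth year floored
to a multiple of 10). Cells below `min_cell_n = 50` records are dropped:
`sigma_hat` from smaller cells is too unstable to regress on, and at the
intended survey scale (thousands of adults per year) such cells occur only
at cohort edges.

The two-step regression then models trends in the cell parameters:

1. position: `mu_hat ~ f(sex, age, year)`;
2. shape: `sigma_hat ~ g(sex, age, year, mu)`, with the observed `mu_hat`
   as the position covariate at fit time and the *predicted* mu at
   projection time (the only mu available in the future).

`age` is the cell's mean age in years; `year` is centred so 2003 = 0, which
keeps year and year² coefficients on interpretable scales; `sex` is
1 = male, 0 = female.

Two year-trend families define scenario bounds. The *linear* family is
polynomial in centred year (optionally quadratic); extrapolated, it can
peak and decline — the best case. The *non-linear* family replaces the year
polynomial with `a − b·exp(−c·year)`; for c > 0 this flattens toward the
asymptote `a` — the worst case, trends never reverse. A fitted c ≤ 0 is
legitimate (the exponential term then grows; the shape model genuinely
selects this on England-like data) and is flagged as non-flattening rather
than rejected.

## Candidate grammar

The published analyses report only the optimal equations, not the searched
set, so the candidate pool is a reconstruction: every term appearing in
either optimal model plus the symmetric completion `sex:year`, closed under
hierarchy (a quadratic requires its linear term, an interaction its mains,
mu² requires mu; mu-terms only in shape models). The mandatory core is
{intercept, sex, age, year structure}. This yields 50 linear / 5 non-linear
position candidates and 150 linear / 15 non-linear shape candidates — the
linear family is deliberately the larger search, matching how a polynomial
grammar composes. Year interactions are offered only in the linear family;
the exponential family carries its entire year dependence in (a, b, c).

## Model selection

Monte Carlo cross-validation: `n_runs` (default 1000) random 80/20 splits
of the cohort-year cells (the rows the regressions actually see), every
candidate fitted on the training part, scored by RMSE on the test part;
the per-run winner is the minimum-RMSE candidate, and the optimal model is
the most frequent winner. Failed fits (rank-deficient designs,
non-convergence) score +infinity so the contest continues; a run in which
every candidate fails is recorded as void and excluded from the
denominator. Ties in the final ranking break toward fewer parameters, then
lexicographic candidate id. Selection is reproducible under the configured
seed.

A property worth understanding before reading ranking tables: when the pool
contains strict supersets of the best term set, the winner's share is a
plurality, not a majority. On a fixed dataset, the realised projection of
noise onto an extra regressor is indistinguishable from signal, so
repeated resampling of the *same* cells cannot reliably separate a true
term set from its one-term extensions — win shares of 10–20% for the top
candidate are normal, and the modal winner among near-equivalent supersets
can flip between datasets. Underfitting candidates (those missing needed
terms) are, by contrast, rejected decisively. Selection is stable in the
number of runs: doubling 1000 to 2000 does not change the optimum on the
packaged fixtures.

## Non-linear estimation

For fixed rate c the exponential model is linear in every other
coefficient, so fitting profiles c (variable projection): inside the
cross-validation loop, c is optimised over a grid on [−0.5, 1.0] (31
points) with golden-section refinement; the public `fit_nonlinear` then
polishes all parameters jointly by Levenberg–Marquardt (tolerances 1e-12)
from multistart values c₀ ∈ {0.01, 0.05, 0.1, 0.5, −0.05, −0.2}. Negative
starts are included because shape models can have genuinely negative rates.
Exponents are clipped at ±50 to keep extreme iterates finite. Standard
errors come from the Jacobian-based covariance `s²(JᵀJ)⁻¹` at the optimum,
pseudo-inverted because the c-direction can be nearly flat; p-values use a
t reference with n − p degrees of freedom.

Fit statistics follow the Gaussian-likelihood conventions: loglik at the
MLE variance RSS/n, AIC = 2k − 2·loglik and BIC = k·ln(n) − 2·loglik with
k the number of mean parameters, deviance = RSS, residual df = n − k. R²
and the F statistic are reported for the linear family only.

## Projection and uncertainty

Per (year, sex, single age 18–100): predict mu, then sigma (floored at
0.01 with a warning if a polynomial shape model goes non-positive under
extrapolation — inspect any run that warns), then five-category
prevalences as lognormal CDF differences at cuts 18.5 / 25 / 30 / 35 kg/m²
(left-closed interior intervals: 25.0 is Overweight). The untruncated
lognormal is used even though input records are filtered to BMI 10–65: at
realistic (mu, sigma) the mass outside that window is negligible.
Aggregation over a population table is a count-weighted mean per group, so
category sums of 1 are preserved exactly. `at_risk` is the BMI ≥ 25 share.

95% intervals: 1000 independent multivariate-normal draws of each model's
coefficient vector about (estimate, covariance), the full projection
recomputed per draw, intervals as 2.5/97.5 percentiles and the point
estimate as the draw mean (the deterministic plug-in projection is reported
alongside — the two differ when the prevalence map is nonlinear in the
coefficients). Position and shape draws are independent because the
two-step fit provides no cross covariance; this slightly understates
interval width where the fits are correlated. Non-PSD covariance inputs
are repaired by clipping negative eigenvalues, with a warning.

## Synthetic data

The generator emulates an annual measurement survey of adults: per year,
`n_per_year` records with uniform integer ages over `age_range`
(default 18–95; an `age_sampler` hook accepts any other age law), sex
Bernoulli(0.5), and BMI = exp(Normal(mu, sigma)) from explicit coefficient
surfaces, evaluated per record. Defaults generate 24 survey years at 8000
adults/year, yielding ≈400 sex-specific cohort-year cells — the scale of
the England analysis — with the published England linear surfaces as
generating truth (the shape surface's mu-terms are evaluated at the true
mu). Configuration with a non-positive sigma anywhere on the covariate
grid is rejected up front, naming the offending cell. One RNG stream per
run makes output byte-identical given (config, seed).

Deliberately not emulated: the multi-stage sampling design, clustering,
non-response weighting, and the real age pyramid. Passing recovery tests
therefore demonstrate correctness of the estimators and pipeline under the
assumed lognormal data-generating process — not robustness to survey
design effects. One consequence of age aggregation is worth noting: a
decade-wide cohort cell's mean log BMI differs from the surface at the
cell's mean age by ~β_age²·Var(age in cell) (order 1e-4 here), a small
systematic residual that extra interaction terms can absorb at very large
n.

The population generator is a synthetic stand-in for an official principal
projection: a smooth adult age profile (flat to ~70, Gaussian taper
beyond), fixed per-age jitter, geometric growth at `growth_rate`
(default 0.003/yr in the pipeline).

## Problem sizes and tolerances in the shipped checks

The test suite fits at 1500 adults/year (24 years, ≈370 cells) for speed
and at the full 8000/year scale for parameter recovery (every coefficient
of both generating surfaces within 3 reported SEs) and end-to-end
validation (fit 1991–2014, score 2015–17; pooled five-category MAE under
3 percentage points; typical values ≈1.2–1.4%). Cross-validated selection
in the end-to-end checks uses 200 runs, which is past the point where the
ranking stabilises on these fixtures. Monte Carlo oracle comparisons use
10⁶ draws with per-category binomial 3-SE agreement, allowing the
by-design false-exceedance rate across simultaneous comparisons (hard cap
at 4–4.5 SE). OLS is checked against an extended-precision
normal-equations solve to 1e-8 per coefficient — extended precision
because near-collinear mu/mu² columns make float64 Gram matrices lose
~1e-7.

## Known limitations

- Scenario labels are assumptions, not forecasts: the linear family
  *encodes* eventual reversal, the exponential family *encodes*
  flattening; data cannot overturn either beyond the fitting window.
- Unweighted regression across cells (cell sizes vary ~50–600); weighted
  fitting is available via the estimators but is not the default, as cell
  noise is small relative to trend structure at survey scale.
- Interval coverage inherits the independence and normality of coefficient
  draws; no survey design effects are propagated.
- The one-standard-error selection rule is not implemented; selection is
  strictly frequency-of-best.
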