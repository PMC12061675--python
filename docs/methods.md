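# Methods

## Growth model and derived characteristics

Stem elongation of each plant-year is modelled by the four-parameter
Richards function y(x) = a(1 + b·e^(−cx))^(−1/d), a monotone sigmoid rising
from 0 to the asymptote a. With the substitution u = b·e^(−cx) the calculus
is closed-form throughout:

* growth rate y′ = (ac/d)·u(1+u)^(−(d+1)/d), maximal at u = d, so
  DayMaxGR = ln(b/d)/c and MaxGR = ac(1+d)^(−(d+1)/d);
* curvature y″ = (ac²/d²)·u(u−d)(1+u)^(−(2d+1)/d); its extrema (zeros of
  y‴) solve u² − d(3+d)u + d² = 0, giving StartLogG and EndLogG at
  u = (d/2)((3+d) ± √((3+d)²−4)).

Because the product of the two roots is d², the logarithmic phase is exactly
symmetric about the inflection on the x axis: (StartLogG + EndLogG)/2 =
DayMaxGR for every valid parameter set. The test suite first confirms every
closed form against numeric oracles that use only curve evaluation
(complex-step first derivative; curvature extrema located as roots of a
5-point-stencil third derivative by bracketed root-finding, accurate to
~1e−11 of the curve time scale) and then enforces them as regression tests.
AUC is adaptive quadrature (scipy `quad`) of the fitted curve over a
configurable window, 0–365 days by default; there is no elementary closed
form for general d. The window choice is a convention: the curve plateaus
well before day 365, so AUC is insensitive to the upper bound but does scale
with it; comparisons should always use one window. The day at 15 cm inverts
the curve in closed form, x = −ln(((a/h)^d − 1)/b)/c, and is undefined when
a ≤ 15 cm (reported as missing).

## Fitting

Per-plant bounded nonlinear least squares (scipy `least_squares`, trust
region reflective, analytic Jacobian) with a data-driven start: a₀ = 1.05 ×
max observed length, d₀ = 1, c₀ from the slope of the log-linearized
logistic on interior points, b₀ solved from the first positive observation.
Bounds: a ∈ (max_obs, 10·max_obs], b ∈ [1e−6, 1e6], c ∈ [1e−4, 1],
d ∈ [0.05, 20]. Because Richards fits are initialization-sensitive, up to 20
restarts jitter (b, c, d) log-uniformly over ±half a decade; a restart only
replaces the incumbent if it improves RSS by >0.1%, and the loop stops after
a minimum of 3 restarts once the fit is essentially exact (R² ≥ 0.995) or
restarts stop helping. Parameter standard errors come from the Gauss–Newton
covariance at the solution.

Fits enter downstream analyses only if they converged, have ≥ 6 points and
R² ≥ 0.8 (all configurable); excluded plant-years are logged with
machine-readable reasons. Non-convergence is a flagged result, not an
exception, so population loops never abort. The (b, c, d) likelihood has a
famously flat ridge: individual parameters can be poorly determined while
the derived characteristics — functionals of the whole curve — remain
stable; standard errors on b and d should be read in that light.

## Thermal time

Degree days above a 10 °C base are computed per day from Tmax/Tmin by
either the simple average, max(0, (Tmax+Tmin)/2 − Tbase), or the
Baskerville–Emin single-sine estimator, which integrates the part of a sine
diurnal course above the base and therefore credits days whose mean is below
base but whose maximum is above. The average method is the default; the
method is recorded in output metadata, and no upper cutoff is applied. Gaps
in the daily record are a hard error — callers must gap-fill explicitly.
Re-expressing a stem series on the thermal axis replaces each measurement
day's x with the accumulated °Cd at that day; on constant-°Cd weather this
rescales the fitted rate c by exactly the daily degree-day sum (verified in
tests).

## Variance components and heritability

The crossed random model y = μ + genotype + block + error is fitted by
direct REML: the error variance is profiled out and the restricted
likelihood maximized over the two variance ratios on the log scale
(Nelder–Mead from an expected-mean-squares start). On balanced data with
interior estimates this reproduces the classical ANOVA estimators to
optimizer precision (~1e−8 observed); when a moment estimate would be
negative the log-scale parametrization enforces the boundary and small
components are clamped to zero. Broad-sense heritability is
H² = V_g/(V_g + V_e), deliberately excluding the block variance from the
denominator. statsmodels MixedLM (variance components with a single dummy
group) serves as an independent cross-check in the tests at loose tolerance;
its default optimizer is not precise enough to serve as the implementation
here.

## Downstream analyses

Pearson correlations are pairwise-complete with two-sided t-distribution
p-values; zero-variance cells are reported as missing with a reason, and no
multiplicity correction is applied. Species comparisons use a type-III ANOVA
(OLS with sum-to-zero contrasts — identical to the classical one-way F for
this single-factor model, and verified against the model-comparison
definition on unbalanced data) followed by Tukey HSD at α = 0.05, compacted
to letter groups by the insert-and-absorb algorithm with letters ordered by
group mean, ties broken by group size then name.

Duration binning partitions plants into half-open intervals [k·w, (k+1)·w)
aligned at multiples of the width w (3–10 d; 10 d default); bins with fewer
than 10 plants are discarded. Within-bin correlations of StartLogG against
dry weight or MaxGR isolate the effect of growth timing from the
rate–duration tradeoff. The extremes table takes the top and bottom
k = round(0.05·N) plants per trait population-wide (stable sort, boundary
ties in row order) and expresses each species' tail membership as a
percentage of that species' total. Composite traits are MaxGR/Duration and
the sum of ascending average ranks of the two, so a high rank sum marks
fast-and-long growers. Geographic regression fits one OLS per coordinate
(latitude, longitude, altitude, plus an optional latitude + altitude² model)
for day-to-15-cm; the selected predictor is the smallest p with ties broken
by adjusted R², or "none" if nothing clears α.

## Synthetic trial generator

The generator is trait-first: per-genotype targets for MaxGR, DayMaxGR and
Duration are drawn from species-specific normal distributions (nine groups
with sizes and 2016-season means/SDs representative of a large *Miscanthus*
diversity trial — calibration targets, not a reproduction of field data) and
the Richards parameters are solved exactly from the targets
(c = ln(u₊/u₋)/Duration; a from MaxGR; b from DayMaxGR; d sampled
log-normally around 1, σ = 0.25). Genotype effects are shared across the 3
blocks; block effects (drawn once per block, centred so the 3-draw lottery
cannot shift the population mean off its calibration target) and residuals
are added per plant, with the residual variance set from the realized
genotype-target variance so the planted H² per trait (defaults 0.77/0.66/
0.65 for MaxGR/DayMaxGR/Duration) is exactly the intended ratio. Infeasible
draws (non-positive Duration, rate outside fit bounds, asymptote below
16 cm) are rejection-resampled with a cap. A configurable latitude effect
(default 1 d per degree from the species' centre) shifts a genotype's whole
trajectory, so day-to-15-cm inherits the geographic signal exactly.

Measurements are the true curve at 12 visit days (default roughly
fortnightly, day 121–304, i.e. May–October) plus i.i.d. Gaussian noise of
SD 5 cm, truncated at zero; an optional positive bias emulates recording the
longest of three stems (off by default). Weather is a sinusoidal temperate
year (annual mean 9.5 °C, amplitude 5.5 °C, ~7 °C diurnal spread, peak near
day 200). Harvest dry weight is κ·AUC·(1 + noise) (κ = 0.05 g per cm·d,
CV 0.3); moisture content is a logistic function of standardized EndLogG
minus standardized MaxGR mapped into [0.2, 0.7], so late-growing slow plants
carry the wettest biomass; subsample wet/dry weights are back-computed so
the moisture arithmetic round-trips exactly. A banded mode replaces the dry
weight with a construction planting a chosen within-Duration-band
correlation with StartLogG, for studying the binned analysis under known
truth.

What the generator does **not** emulate: spatial field trend, year effects,
genotype-by-environment interaction, non-normal trait distributions,
missing-plant patterns, flowering/senescence-driven departures from a pure
sigmoid, and serial correlation of measurement errors within a plant.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated generating model, not robustness to all field realities.

## Known limitations and numerical caveats

* **Refitted Duration is biased upward at realistic noise.** Per-plant
  4-parameter Richards fits of ~12-visit series with 5 cm noise overestimate
  Duration by ≈ +2–3% on average (d̂ is pulled along the flat likelihood
  ridge). The bias is a property of per-plant nonlinear least squares, not of
  this implementation: R's minpack.lm `nlsLM` shows the same shift on
  identical replicate data. MaxGR refits are nearly unbiased. Consequently a
  simulate-then-refit round trip reproduces the generator's MaxGR calibration
  within sampling error but lands ~3% high on Duration; cohorts fitted at
  different noise levels or visit densities should not have their Durations
  compared naively.
* The balanced-data REML = ANOVA identity used as a cross-check holds only
  for interior estimates; replicates with a negative moment estimate hit the
  REML boundary and legitimately deviate.
* Duration-bin anchoring at multiples of the bin width, the round-half-up
  5% tail size with minimum 1, stable-sort tie-breaking at tail boundaries,
  ascending rank direction for the composite rank sum, and nearest-day
  rounding of DayMaxGR for reporting only, are all conventions chosen once
  and documented here; alternatives would change third decimals, not
  conclusions.
* Problem sizes in the test suite and acceptance script (500-curve sweeps,
  100-plant fit recovery, 20 replicates of 200×3 heritability trials, one
  900-genotype calibration round trip) were chosen to make sampling error
  small relative to the tolerances being checked.
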