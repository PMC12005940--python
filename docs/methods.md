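# Methods

## Design and estimand

The pipeline implements a time-stratified case-crossover analysis of
short-term ambient PM2.5 and mortality, with parcel-level structural air
exchange rate (AER) as a multiplicative effect modifier. Each decedent
contributes one matched set (stratum): the case day (date of death) and
referent days taken every third day before or after the case day within the
same calendar month and year. Because "every third day within the month" is
exactly the case day's day-of-month residue class mod 3, the referent sets
partition each month into three fixed classes; a 30-day month gives each
case 9 referents, and on average exactly 9 across case days. Conditioning on
the class makes the per-stratum intercept — and with it every time-invariant
or slowly varying personal and spatial confounder — drop out of the
likelihood.

The conditional-logistic model for stratum *i*, day *j* is

    logit p_ij = alpha_i + beta1 * PM_ij + theta3 * PM_ij * AER_i + C_ij' gamma

with PM in units of 10 µg/m³ (lag 0–1 mean of daily concentrations),
AER_i the stratum parcel's AER for the case day's season, and C the
time-varying confounders: lag 0–1 daily mean temperature (per 10 °C, the
daily mean approximated as (tmin+tmax)/2), lag 0–1 relative humidity (per
10 %), and day-of-week as six indicators with Sunday as reference. theta3 is
a log-odds per 10 µg/m³ per unit (hour⁻¹) AER; exp(theta3) is the per-unit
interaction odds ratio. Warm season is May–October, cool November–April;
strata cannot straddle seasons because they live within one month. The
lag-1 day of a referent on the 1st or 2nd of a month may fall in the
previous month — the month constraint binds referent days, not their
exposure windows.

## AER model

Structural AER comes from the LBNL infiltration framework: a log-linear
*normalized leakage* regression on building vintage and floor area,

    NL = exp(b0 + b_year * year_built + b_area * area [+ low-income offset]),

times a stack/wind infiltration factor

    s = sqrt(f_s * stories * |T_in - T_out| + f_w * (shielding * wind)^2),

scaled to conditioned-volume height: AER = NL * s * h_ref / (stories * h_story).
The one-story stack coefficient grows linearly with stack height in stories,
the standard LBNL pattern (≈0.015, 0.030, 0.045 (h⁻¹)²/°C for 1–3 stories).
Multifamily parcels use per-unit floor area (building area / housing units
when ≥ 2 units) in the leakage regression and half the building's stories as
the representative unit's stack height; nonresidential parcels apply a
leakage multiplier (default 0.5). Only envelope leakage is modelled — no
window opening, no mechanical ventilation or air conditioning.

Defaults (all config-exposed, `AERConfig`): intercept 11.78, −0.0059 per
year built, −0.0004 per m², f_s = 0.015, f_w = 0.0065, indoor set point
20 °C both seasons, story height 2.5 m, wind shielding 1. The leakage
coefficients are a Chan-type vintage/size regression chosen once to place
the synthetic AER distribution at realistic magnitudes for a New England
housing stock (population mean ≈ 0.6/h; cool-season means around 0.7–1.0/h,
warm around 0.2–0.5/h) under the default seasonal normals (cool: 5 m/s,
2 °C; warm: 3.5 m/s, 17 °C). The qualitative orderings — cool above warm
for every parcel, nonresidential below residential — follow from the
structure, not the particular constants, and are what the tests assert. The
"land use" shielding enters as an optional multiplicative factor on wind
speed; low-income adjustment as an additive log-NL offset (default 0).
AER = 0 exactly is legal (no truncation).

## Linkage and exclusions

Deaths are matched to the nearest parcel by point-to-centroid Euclidean
distance (parcels are points in the synthetic pipeline), ties broken by
smallest parcel id. Three filters then apply, in order: matches to excluded
nonresidential land-use categories (agriculture/recreation, educational,
industrial/warehouse/utilities); matches to parcels with zero recorded
building area; matches farther than 10 m. Because one record can fail
several filters, the report carries both sequential counts (first applicable
filter; sums to the total excluded) and overlap-aware counts (every filter a
record fails); percentages recompute from raw counts to two decimals.

## Conditional likelihood and inference

The conditional log-likelihood
`sum_i [x_case·beta − log sum_j exp(x_ij·beta)]` is maximised directly by
Newton–Raphson from beta = 0 with analytic gradient and Hessian, segmented
(per-stratum) reductions, and log-sum-exp stabilisation. Step-halving (up to
20 halvings) guards the ascent; the likelihood is concave, so this converges
globally unless the data are separated, which is detected when a coefficient
passes a configurable bound (default 15 on the log-odds scale) with a
non-vanishing gradient and raised as an error rather than reported as a fit.
Convergence requires max |gradient| < 1e-8 and relative log-likelihood
change < 1e-10. The covariance is the inverse observed information at the
optimum; strata with no within-stratum covariate variation are counted as
non-informative but retained (they shift the likelihood by a constant).
Effect modification is tested by the df = 1 likelihood-ratio test of the
product term.

Linearity checks replace a linear term with an unpenalised cubic B-spline
basis (default 4 interior knots at quantiles, boundary knots at the data
range) and LR-test the extra curvature at alpha = 0.05. The raw basis is a
partition of unity, whose column sum is a stratum constant the conditional
likelihood cannot identify, so the first basis column is dropped; the test
df is (basis columns − 1), the dimension of the spline space modulo
constants beyond the linear term. This is an unpenalised approximation to a
penalised-spline check: in sparse covariate tails an unpenalised basis
column can separate, which surfaces as a `SeparationError` rather than a
spurious p-value.

Reporting: percent change per 10 µg/m³ at AER = a is
100·(exp(theta1 + a·theta3) − 1) with delta-method variance
V11 + a²V33 + 2aV13 on the log-odds scale and Wald 95 % limits
exponentiated. Anchors default to the 25th/75th percentiles of the analysis
subset's per-stratum AER (linear-interpolation quantiles), overridable to
the study-population values 0.270/0.854 per hour. The identity
exp(theta3)^(a2−a1) = (1+pc(a2)/100)/(1+pc(a1)/100) links the interaction OR
and any two percent changes; `report` exposes both directions.

## Synthetic cohort

The generator emulates the three inputs. Parcels: configurable mixture of
residential types 1–5 (single family, duplex/triplex, small/large
apartments, multiuse) and nonresidential parcels (default 42/10/8/6/4/22 %,
plus 8 % in excluded categories), vintages uniform over 1850–2015, lognormal
floor areas (median 180 m², larger for apartments and nonresidential), 5 %
zero-area records, 3 % of nonresidential parcels flagged affordable housing.
Exposures per grid cell: log-PM2.5 = summer-peaking seasonal cycle
(geometric mean 8 µg/m³, log-amplitude 0.25) plus a stationary AR(1)
(phi = 0.6, marginal sd 0.5); temperature a sinusoid (mean 9.4 °C, amplitude
12.5 °C) with AR(1) noise and an 8 °C diurnal spread; humidity autocorrelated
noise around 64.5 % clipped to [0, 100]. These centre on the study
population's printed exposure summaries.

Case days use exact within-month conditional sampling: draw a (parcel,
month) stratum uniformly — parcels from the AER-eligible pool, months fully
covered by the exposure span including the lag-1 lead-in day — then the day
within the month with probability softmax(eta_d), where eta_d is exactly the
analysis model's linear predictor. Default planted truth: theta1 = 0.02
(OR 1.02 per 10 µg/m³), theta3 = 0.14 (interaction OR 1.15 per unit AER),
0.005 per 10 °C and per 10 % RH, and a small day-of-week pattern with Sunday
fixed at 0 — the magnitudes the study population reports. Because sampling
is conditional within the month and the referent classes partition the
month, the conditional-logistic estimand equals these parameters by
construction. Geocodes are the parcel centroid plus radial jitter (90 %
within 1 m, 8 % within 1–10 m, 2 % at 10–25 m), so the >10 m exclusion has a
planted ~2 % rate; in-hospital flags at 40 %; causes 33.4 % CVD, 11.1 %
respiratory. All randomness derives from one master seed via per-entity
substreams (stable CRC32 hashing into a `SeedSequence`), making outputs
independent of iteration order.

What the generator does **not** emulate: spatial autocorrelation of PM2.5
across cells, real street/parcel geography, parcel polygons (distance is
point-to-centroid), mortality displacement, demographic covariate structure,
or ICD-level cause detail. Passing recovery tests therefore show the
estimator and design machinery are correct under the stated generating
process, not that any particular real-data result is reproduced.

## Problem sizes and numerical choices

Replicated simulations use: 50,000 deaths for point recovery (estimates
within 3 SEs of truth); 200 replicates of 2,000 deaths for CI calibration;
500 replicates of 1,000 deaths for the null rejection rate of the df = 1
product-term LR test; 500 stratum-resampling bootstrap refits of an
8,000-stratum fit for the delta-vs-bootstrap interval comparison; spline
power and type-I checks at 3,000 and 200×250 strata. Wald intervals are
mildly anticonservative at small stratum counts, as expected for
curvature-based standard errors, and approach nominal coverage as strata
grow. Ties in nearest-parcel matching break to the smallest parcel id;
quantiles use linear interpolation; dates are ISO-8601 throughout.

## Known limitations

Only the every-third-day referent scheme is implemented (other schemes are a
documented extension point); exposure lags other than 0–1 are available only
through the lag-table machinery, not first-class options; the linearity
check is unpenalised rather than penalised-spline; no robust/sandwich
variance, no random effects. The AER coefficients shipped as defaults are
plausible-magnitude placeholders for the authoritative published regression
constants, which users with access to them should set via `AERConfig`.
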