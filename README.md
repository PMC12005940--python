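# aerxover

Effect modification of short-term ambient PM2.5–mortality associations by
parcel-level structural **air exchange rate (AER)** — a reusable,
fully-tested implementation of the analysis pipeline, exercised end to end on
synthetic cohorts with known truth.

## Who this is for

Environmental epidemiologists studying how building ventilation shapes the
health impact of ambient air pollution. The ambient concentration a monitor
or model reports is not the concentration people breathe indoors: leakier
buildings let more ambient PM2.5 infiltrate, so the same outdoor day can
carry different doses across homes. Treating the building envelope's air
exchange rate as an effect modifier quantifies that heterogeneity.

## What the package does

1. **`aerxover.aer`** — structural AER (hour⁻¹) per parcel and season from
   the LBNL physics-based infiltration model: normalized leakage
   `NL = exp(b₀ + b_year·year_built + b_area·area)` combined with the
   stack/wind infiltration factor
   `s = √(f_s(stories)·|T_in − T_out| + f_w·wind²)` and scaled by the
   conditioned-volume height. Multifamily parcels use per-unit floor area;
   nonresidential parcels a configurable leakage multiplier. Window opening
   and HVAC are deliberately out of scope.
2. **`aerxover.linkage`** — nearest-parcel matching of geocoded deaths, the
   exclusion filters (excluded land-use categories, zero building area,
   distance > 10 m) with sequential *and* overlap-aware accounting, and
   single-family/multifamily classification.
3. **`aerxover.design`** — time-stratified case-crossover strata: the case
   day plus referent days every third day within the same calendar month
   (≈ 1:9 matching), lag 0–1 exposure means, warm (May–Oct) / cool
   (Nov–Apr) season split, and the <29 °C and out-of-hospital sensitivity
   filters.
4. **`aerxover.clogit`** — conditional logistic regression

   logit p_ij = α_i + β₁·PM_ij + θ₃·PM_ij·AER_i + C_ijᵗγ

   maximised directly by Newton–Raphson (analytic gradient/Hessian,
   log-sum-exp stabilised, separation detection), with likelihood-ratio
   tests and an unpenalised B-spline linearity check.
5. **`aerxover.report`** — percent change in mortality odds per 10 µg/m³
   PM2.5 at AER percentiles, `100·(exp(θ₁ + a·θ₃) − 1)`, with delta-method
   CIs, the per-unit interaction OR `exp(θ₃)`, and stratified summary
   tables.
6. **`aerxover.synthetic`** — parcels, daily exposure series and death
   records with exact within-month conditional case-day sampling, so the
   conditional-logistic estimand equals the planted parameters and
   recovery/calibration tests are sharp.

## Worked example

```python
import aerxover as ax

inputs = ax.make_study_inputs(n_parcels=2000, n_cells=4,
                              span=("2009-12-01", "2011-12-31"), seed=1)
built = ax.simulate_and_design(inputs, n_deaths=50_000, seed=2)
fit = ax.fit_interaction(built.rows)
print(fit.summary().loc[["pm10u", "pm10u:aer"]].round(4))
for a in (0.270, 0.854):
    est = ax.percent_change_at(fit, a)
    print(f"AER {a:.3f}/h: {est.percent_change:+.2f}% "
          f"({est.ci_low:+.2f}, {est.ci_high:+.2f})")
```

prints

```
             coef      se      or  or_low  or_high       p
pm10u      0.0039  0.0195  1.0039  0.9662   1.0431  0.8425
pm10u:aer  0.1520  0.0390  1.1641  1.0785   1.2565  0.0001
AER 0.270/h: +4.59% (+2.13, +7.12)
AER 0.854/h: +14.30% (+9.90, +18.87)
```

The deaths were simulated with a true log-odds of 0.02 per 10 µg/m³ at
AER = 0 and an extra 0.14 per 10 µg/m³ per unit AER (interaction OR 1.15);
the fitted coefficients recover both within sampling error (the planted
values sit inside both Wald intervals), and the percent change rises with
AER as planted. A `click` CLI (`aerxover simulate / aer /
link / design / fit / report`) drives the same stages over CSV files.

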