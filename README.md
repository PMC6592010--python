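# expvat

Objective estimation of the **ventilatory anaerobic threshold (VAT)** from
breath-by-breath cardiopulmonary exercise test (CPX) data, for exercise
physiologists and cardiac-rehabilitation researchers who want a reproducible
alternative to visual V-slope reading.

## The method

During an incremental (ramp) exercise test, CO2 output and ventilation
accelerate relative to O2 uptake once lactic acid buffering begins. `expvat`
fits an exponential trend

```
y = b · a^x        (x = VO2 in mL/min; y = VCO2 in mL/min, or VE in L/min)
```

to the ramp-phase data by log-linear least squares and derives two
closed-form thresholds from the fitted curve's geometry:

* **expVAT(VCO2)** — the VO2 where the tangent to the fitted V-slope is
  parallel to the R = 1 line (instantaneous dVCO2/dVO2 = 1):

  `expVAT(VCO2) = ln(1 / (b·ln a)) / ln a`

* **expVAT(VE)** — the VO2 where the tangent to the fitted VO2–VE curve
  passes through the origin, which is also the nadir of the fitted
  ventilatory equivalent VE/VO2:

  `expVAT(VE) = 1 / ln a`   (independent of b)

A smaller base `a` (a shallower curve) means a higher threshold. The
companion **oxygen uptake efficiency slope (OUES)** — the OLS slope of VO2
on log10(VE), or the log10(VCO2) variant — is computed alongside, as are:

* quality control: iterative lower-tail Smirnov–Grubbs screening of fit
  quality, and the pre-threshold V-slope validity rule (a whole-test linear
  V-slope below 1.105 = 0.901 + 2·0.102 means the threshold was likely
  never reached);
* agreement statistics: Bland–Altman limits of agreement (±1.96·SD of
  paired differences), pairwise-complete correlation matrices, and
  Williams's test for comparing two dependent correlations;
* truncation sensitivity analyses (fraction-of-ramp or VO2-ceiling cuts)
  and paired pre/post change reports;
* a seeded breath-by-breath ramp simulator whose V-slope is two-segment
  linear with a known knot — deliberately not the fitted exponential — so
  every estimator can be validated against ground truth.

## Worked example

```sh
python examples/single_test.py
```

```
true threshold (generator):       1100 mL/min
expVAT(VCO2):                     1029 mL/min
expVAT(VE):                        981 mL/min
V-slope exponential base a:      1.00115
OUES(VE):                         2186 mL/min per decade
OUES(VCO2):                       1936 mL/min per decade
highest VO2:                      2055 mL/min
relative expVAT(VCO2):            50.1 % of peak
%predicted peak HR:               94.3 %
QC flags:                     none
```

The simulated subject's true threshold is 1100 mL/min; both closed-form
estimates land within ~7% of it, the exponential base sits in the
1.001–1.002 range typical of adult ramp tests, and the empty flag set means
the fit quality and the whole-test V-slope validity screen both passed.
The other scripts in `examples/` walk through cohort-level threshold
recovery, truncation sensitivity, method agreement and QC screening.

From Python the same computation is three lines:

```python
import expvat as ev
test = ev.read_cpx_table("subject.csv")   # columns t, vo2, vco2, ve, ...
est = ev.evaluate_test(test)              # VatEstimates with QC flags
```

A thin CLI wraps the same functions:

```sh
expvat simulate --n 20 --seed 1 --out cohort/
expvat batch cohort/manifest.csv --out cohort_table.csv
expvat compute cohort/sim000.csv
expvat compare pre_manifest.csv post_manifest.csv --truncate-fraction 0.75
```

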