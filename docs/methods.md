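# Methods

## The estimation model

Ramp-phase gas exchange is summarized by an exponential trend
`y = b·a^x`, with VO2 (mL/min) as `x` and either VCO2 (mL/min) or VE
(L/min) as `y`. The fit is ordinary least squares of `ln(y)` on `x`
("log-linear"): `a = exp(slope)`, `b = exp(intercept)`. This is the
exponential-trend convention of spreadsheet statistics tools and is the
package default; a true nonlinear least-squares fit on the original scale
(scipy `curve_fit`, initialized from the log-linear solution) is available
via `method="nonlinear"`. On noise-free exponential data the two coincide;
on real data they weight breaths differently (log-linear downweights large
absolute residuals at high VO2). Fit quality `r_fit` is the Pearson
correlation between observed and fitted values on the original scale.

Two thresholds follow in closed form:

* `expVAT(VCO2) = ln(1/(b·ln a))/ln a` — where the fitted V-slope's
  derivative `b·a^x·ln a` equals exactly 1, i.e. the tangent parallel to
  the R = 1 line. Defined only for `a > 1` and `b·ln a < 1` (otherwise the
  tangency point lies at non-positive VO2); undefined cases are returned as
  missing with the `a_not_gt_1` flag rather than raised, since cohort
  workflows need per-subject missingness.
* `expVAT(VE) = 1/ln a` — where the tangent to the fitted VO2–VE curve
  passes through the origin; algebraically the minimizer of the fitted
  ventilatory equivalent `(b·a^x)/x`, hence the fitted VE/VO2 nadir.
  Independent of `b`.

Because VO2 enters the exponent in mL/min, physiological `a` values sit
just above 1 (≈1.0010–1.0020); both thresholds are steeply decreasing in
`a`. Breaths are fitted raw and unweighted — no interpolation, time
averaging or breath averaging is applied by default (an optional centred
n-breath moving average exists but is off everywhere).

OUES is the OLS slope of VO2 (mL/min) on log10 of the ventilatory channel:
VE in L/min (the conventional index) or VCO2 in mL/min (the analogous
variant). Base-10 is used because OUES is conventionally reported per
decade of ventilation; the slope is invariant to the channel's unit scale,
which only shifts the intercept.

## Quality control and agreement statistics

* **Fit screening.** Fit-quality `r` values of a cohort are screened with
  an iterative Smirnov–Grubbs test, lower tail, default α = 0.001: the
  smallest value is tested with `G = (mean − min)/SD` against
  `G_crit = ((N−1)/√N)·√(t²/(N−2+t²))`, `t` the upper `α/N` quantile of
  `t_{N−2}`, removed if it exceeds, and the test repeated. The lower tail
  is the right default because artifacts and short tests depress `r`; zero
  spread excludes nothing. Flagged subjects keep their estimates but carry
  `poor_fit_outlier`.
* **Validity rule.** A whole-test linear V-slope below 1.105 (the
  pre-threshold slope mean 0.901 plus two SDs, 2·0.102) indicates the
  threshold was likely never reached; `evaluate_test` applies this to the
  full ramp and sets `pre_vat_slope_below_threshold`. The same check can be
  applied to any segment (e.g. data below an externally supplied visual
  threshold) via `pre_vat_slope_check`.
* **Agreement.** `bland_altman` reports the mean paired difference, its
  sample SD (n−1) and the limits-of-agreement half-width 1.96·SD, with
  pairwise-complete handling of missing members so every comparison uses
  its maximal n. `williams_test` compares two dependent correlations
  sharing a variable with the standard t on n−3 degrees of freedom;
  `correlation_matrix` reports pairwise-complete Pearson r with per-pair n.
  Paired pre/post tables delegate the paired t-test to scipy.
* **Sanity bound.** An estimate above 1.5× the observed highest VO2 is
  flagged (`implausible_expvat`) but not erased — extrapolated tangency
  points are the known failure mode in subjects with high exercise
  tolerance, and erasing them would hide the problem from the report.

"Highest" values are by default the plain maximum over ramp breaths
(window = 1), matching the last-highest-value convention for submaximal
protocols; a configurable trailing rolling-mean window is available because
breath-by-breath maxima overshoot under noise.

## The simulator

`simulate_subject` generates breath-by-breath ramp tests from a piecewise
model that deliberately does **not** match the fitted exponential, so tests
exercise the estimators as they are used on real data — as an exponential
summary of threshold-shaped gas exchange — rather than refitting their own
generating model:

* VO2 rises linearly through the ramp from its resting level; warmup
  breaths hold resting values.
* VCO2 is two-segment linear in VO2: slope `s1` (default 0.90, the
  pre-threshold V-slope) below the true threshold, `s2` (default 1.40)
  above, continuous at the knot. The knot is the ground-truth threshold.
* VE is linear in VCO2 with a positive intercept (defaults 3 L/min + 28
  L per L of VCO2). The intercept makes VE/VO2 fall before the knot and
  rise after it — its nadir sits exactly at the knot — which is the
  geometry the VE-based estimator needs; dead-space dynamics and the
  respiratory compensation point are not modeled.
* Breaths arrive every ~2 s (±20% uniform jitter); each gas channel gets
  independent multiplicative lognormal noise with unit mean and 4% CV
  (breath-to-breath variability scales with the signal). HR rises linearly
  with VO2 and is left noise-free.

Defaults describe a healthy adult: resting VO2 300 mL/min, 550 s ramp to a
peak just under 2000 mL/min, threshold 1100 mL/min (~55% of peak), peak HR
165. `simulate_cohort` draws per-subject thresholds uniformly over
450–1400 mL/min and sets each subject's ramp so the threshold sits at a
Normal(0.575, 0.04) fraction of peak — reproducing the strong
threshold–capacity correlation of real cohorts — with jittered slopes,
resting VO2, duration and peak HR, clipped to physiological bounds.
Everything is reproducible from a single seed (identical seed ⇒ identical
cohort within this implementation; cross-library bit-exactness is not
promised).

What passing tests on this generator do and do not show: they validate the
estimators' geometry, their ranking of subjects, and their qualitative
duration sensitivity, under idealized piecewise kinetics with stationary
multiplicative noise. They do not capture hyperventilation artifacts,
oscillatory breathing, RER drift, or the above-threshold respiratory
compensation steepening of VE — so quantitative biases on real tests can
differ from the simulated ones.

## Truncation analyses

"First 75% of the data" is implemented as a count-based cut of ramp breaths
(`ceil(f·n)`), which coincides with a time cut under near-uniform breath
intervals; rest/warmup samples are untouched and sample values never
altered. VO2-ceiling truncation locates the first crossing of an 8-breath
trailing rolling mean of VO2 (raw breath VO2 is non-monotone under noise)
and keeps everything up to it. Truncations leaving fewer than 10 ramp
breaths are insufficient data.

On the default cohort, 75% truncation moves expVAT(VCO2) by about −10% and
expVAT(VE) by about −8% (seeded runs in `examples/truncation_sensitivity.py`
and the acceptance script): the VCO2-based threshold is the more
duration-sensitive index, the VE-based one the more robust, matching the
qualitative asymmetry expected from their geometry (the V-slope's
post-threshold steepening carries most of the information the VCO2 tangency
uses).

## Numerical choices and edge cases

* Log-linear OLS uses `numpy.polyfit`; degenerate regressors (zero
  variance) raise a fit error, non-positive y a domain error, and fewer
  than 10 ramp breaths insufficient data.
* Pearson r is reported as NaN when either side has zero variance rather
  than raising.
* Grubbs screening and Williams's test are implemented in-package (no
  installed library provides the iterative screen or the dependent-
  correlations t); both are verified against independently coded formula
  oracles in the test suite.
* CSV round-tripping uses shortest-representation floats on write and
  round-trip float parsing on read, so write→read preserves samples bit
  for bit.
* Estimator-level problems never raise inside `evaluate_test`; they
  surface as flags so batch tables keep one row per subject.

## Known limitations

* The exponential is a summary, not a breakpoint model: on two-segment
  data it systematically underestimates the knot by a few percent
  (≈−5% mean on the default cohort), and the bias depends on where the
  knot sits in the observed range. The estimators are best used for
  ordering subjects and tracking within-subject change.
* Noise on the VO2 regressor attenuates the fitted slope
  (errors-in-variables), biasing thresholds upward at high noise; at
  default noise this effect is small, but it means estimator error about
  ground truth is not a monotone function of noise level — only the
  noise-induced scatter about the estimator's own noise-free limit is.
* Visual threshold determination is out of scope: an externally determined
  visual VAT is consumed as an input column only, and the simulator's
  "visual" readings are synthetic stand-ins (truth times lognormal noise).
* Proprietary vendor binary formats, real-time acquisition and ECG/BP
  channels are not handled.
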