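"""Agreement between the objective estimate and a visual-style reading.

Attaches a noisy reading of the true threshold to each simulated subject
(a synthetic stand-in for a human visual determination), then compares it
with expVAT(VCO2) via limits of agreement and dependent-correlation tests.
"""

import numpy as np

import expvat as ev

cohort = ev.simulate_cohort(60, seed=33, vvat_cv=0.07)
vvat, exp_v, peak = [], [], []
for test, _ in cohort:
    e = ev.evaluate_test(test)
    if e.expvat_vco2 is not None and test.meta.vvat is not None:
        vvat.append(test.meta.vvat)
        exp_v.append(e.expvat_vco2)
        peak.append(e.highest_vo2)

rep = ev.bland_altman(exp_v, vvat)
print(f"n pairs:            {rep.n}")
print(f"mean difference:    {rep.mean_diff:+.0f} mL/min")
print(f"limits of agreement: +-{rep.loa_half_width:.0f} mL/min (1.96*SD)")
print(f"Pearson r:          {rep.pearson_r:.3f}")

r12 = np.corrcoef(peak, exp_v)[0, 1]   # peak VO2 vs objective estimate
r13 = np.corrcoef(peak, vvat)[0, 1]    # peak VO2 vs visual-style reading
r23 = rep.pearson_r
w = ev.williams_test(r12, r13, r23, rep.n)
print(f"r(peak, expVAT)={r12:.3f}  r(peak, vVAT)={r13:.3f}")
print(f"Williams t={w['t']:.2f}, p={w['p']:.3g} (df={w['df']})")
print()
print("The limits of agreement quantify how far an individual objective")
print("estimate may sit from a visual reading; the Williams test asks")
print("whether the objective estimate correlates better with exercise")
print("capacity than the visual reading does, on the same subjects.")
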