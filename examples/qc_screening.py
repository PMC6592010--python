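"""Cohort quality control: fit-outlier screening and validity flags.

Corrupts one simulated subject with gross breath artifacts, then shows the
iterative lower-tail Grubbs screen on fit quality catching exactly it, and
the pre-threshold slope rule flagging a test that never reached threshold.
"""

import numpy as np

import expvat as ev

tests = [t for t, _ in ev.simulate_cohort(15, seed=8)]

rng = np.random.default_rng(0)
bad = tests[0]
tests[0] = ev.CpxTest(meta=bad.meta, protocol=bad.protocol, samples=tuple(
    ev.BreathSample(t=s.t, vo2=s.vo2, vco2=s.vco2 * float(rng.lognormal(0, 0.5)),
                    ve=s.ve, hr=s.hr, work_rate=s.work_rate, phase=s.phase)
    for s in bad.samples))

ests = ev.evaluate_cohort(tests, grubbs_alpha=0.001)
print("subject   fit r (V-slope)  flags")
for e in ests[:5]:
    print(f"{e.subject_id}    {e.r_vslope:.4f}          {sorted(e.qc_flags) or '-'}")
print(f"... flagged {sum(1 for e in ests if e.qc_flags)}/{len(ests)} subjects")

# a test that never crosses the threshold: shallow linear V-slope throughout
vo2 = np.linspace(300, 900, 120)
flat = ev.CpxTest(samples=tuple(
    ev.BreathSample(t=i, vo2=v, vco2=0.88 * v, ve=0.028 * 0.88 * v + 3)
    for i, v in enumerate(vo2)))
est = ev.evaluate_test(flat)
print(f"\nsub-threshold test: linear V-slope {est.pre_vat_slope:.3f} "
      f"(< 1.105) -> flags {sorted(est.qc_flags)}")
print()
print("The Grubbs screen removes subjects whose exponential fit quality is")
print("an outlier (artifacts, too little data); the 1.105 slope rule marks")
print("tests where the threshold was likely never reached, so no")
print("exponential threshold should be trusted for them.")
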