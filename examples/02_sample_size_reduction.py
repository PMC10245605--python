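"""Measure the sample-size reduction from covariate adjustment.

For the same scenario, Monte-Carlo power curves of the unadjusted and
covariate-adjusted Wald tests are probed over n; the even sample sizes
reaching 80% power give the observed reduction R2_obs = 1 - Nadj/N0.
With C=0.65 and 90% incidence, adjustment shaves roughly a quarter to
a third off the required enrollment. (A few minutes of computation.)
"""
from covadjust import TrialScenario, calibrate, find_sample_sizes_paired

scenario = TrialScenario(theta=0.7, w=1.5, d=0.01,
                         Lambda_target=0.9, C_target=0.65)
cal = calibrate(scenario)
res = find_sample_sizes_paired(cal, seed=1, reps=2000)
print(f"unadjusted analysis: N0   = {res.N0}")
print(f"adjusted analysis:   Nadj = {res.Nadj}")
print(f"observed reduction R2_obs = {100 * res.R2_obs:.1f}%")
print("\npower probes (both analyses share each replicate cohort):")
print(res.probes.to_string(index=False))
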