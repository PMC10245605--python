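"""Semi-synthetic trial simulation anchored on an HCC-like cohort.

Generates the synthetic stand-in for the resected-HCC cohort (n=328,
5-year death incidence ~49%, clinical C-index ~0.65 rising to ~0.70 with
the continuous risk score), fits the generative Cox model, and measures
how much adding the score to the adjustment set (on top of tumor staging
and ECOG) reduces the sample size needed for 80% power at theta=0.72.

The parametric cross-check (Fleiss with the reduction surface at
incidence ~0.5) puts the expected reduction near 13%; any single
328-patient cohort scatters around that because the fitted coefficients
— and hence the generative model — inherit its sampling noise.
(A few minutes of computation.)
"""
import numpy as np

from covadjust.semisynthetic import (generate_surrogate_cohort,
                                     run_semisynthetic_reduction)

table = generate_surrogate_cohort(rng=np.random.default_rng(5))
print(f"surrogate cohort: n={len(table)}, "
      f"observed death fraction {table['event'].mean():.1%}")

res = run_semisynthetic_reduction(table, theta=0.72, n_reference=760,
                                  reps=1500, seed=0)
print(f"N at 80% power, clinical adjustment only: {res['N_clinical']}")
print(f"N at 80% power, clinical + risk score:    {res['N_with_score']}")
print(f"reduction from adding the score:          "
      f"{100 * res['reduction']:.1f}%")
print(f"absolute power gain at N_clinical:        "
      f"{100 * res['power_gain_at_N_clinical']:.1f} pp")
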