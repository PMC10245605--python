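# covadjust

Monte-Carlo study of **covariate adjustment in time-to-event randomized
trials**: how much smaller can a trial be, at the same statistical
power, when the Cox analysis of the treatment effect adjusts for a
prognostic baseline covariate?

The package is written for trial statisticians and methods researchers.
It simulates two-arm trials from a Weibull proportional-hazards model

    h_i(z) = θ^z · exp(κ + β x_i),   T_i = (E_i / h_i)^{1/w},   x_i ~ N(0,1),

with exponential drop-out and administrative censoring at the end of
follow-up, and calibrates the auxiliary parameters (κ, β) so the control
arm attains a prespecified cumulative incidence Λ and covariate C-index
C. Power of the unadjusted and covariate-adjusted Wald tests is
estimated by simulation; the even sample sizes N₀ and N_adj reaching the
target power give the observed reduction

    R²_obs = 1 − N_adj / N₀ .

Around that core the package provides: a panel of eight survival R²
measures (Cox–Snell, event-count and Xu–O'Quigley explained-randomness
variants, and four explained-variation measures including the
Royston–Sauerbrei D-based one) with the generalized Fleiss prediction
N_adj = N₀(1 − R²); eligibility-broadening experiments comparing
restricted and broad enrollment at matched event counts; and a
semi-synthetic workflow that simulates trials from a Cox model fitted on
a cohort table (with a calibrated synthetic stand-in for the
hepatocellular-carcinoma cohort it emulates, whose original data are not
public).

## Worked example

```python
import numpy as np
from covadjust import TrialScenario, calibrate, find_sample_sizes_paired

scenario = TrialScenario(theta=0.7, w=1.5, d=0.01,
                         Lambda_target=0.9, C_target=0.65)
cal = calibrate(scenario)
print(cal.kappa, cal.beta)        # -1.3761  0.5789
res = find_sample_sizes_paired(cal, seed=1, reps=2000)
print(res.N0, res.Nadj, res.R2_obs)   # 424  304  0.2813
```

A covariate with C-index 0.65 in a 90%-incidence indication cuts the
required enrollment from 424 to 304 patients — a 28.1% reduction —
purely by being included in the analysis model. The same pipeline at
10% incidence yields only a few percent: the value of adjustment is
driven jointly by the covariate's prognostic strength and by how many
patients actually have events before follow-up ends.

More narrated examples live in `examples/` (calibration, reduction
surface, R² measures, eligibility broadening, semi-synthetic cohort),
and a thin CLI mirrors them:

```bash
covadjust calibrate --c-index 0.65 --incidence 0.9 --shape 1.5
covadjust reduction --incidence 0.9 --c-index 0.65 --reps 2000 --seed 1
covadjust surrogate --n 328 --seed 5 --out hcc.csv
```

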