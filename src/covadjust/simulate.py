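"""Cohort generation from a calibrated Weibull PH trial scenario.

Event times follow the inverse-transform construction
``T = (-ln U / h)^(1/w)`` with hazard multiplier
``h = theta^z * exp(kappa + beta x)``; drop-out times are exponential
with rate ``d`` (absent when ``d = 0``), and every patient still at risk
at the follow-up horizon is administratively censored there. Treatment
is assigned as an exact half-split shuffled against patient order, so
both arms always hold the same number of patients (control gets the
extra patient when ``n`` is odd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import CalibratedScenario

_CLIP = 700.0


@dataclass
class Cohort:
    """Per-patient arrays of one simulated trial.

    ``x`` is an (n, q) covariate matrix (q = 1 for parametric
    simulations); ``z`` the arm indicator (0 control, 1 treated);
    ``time``/``event`` the observed right-censored outcome. The latent
    ``t_event`` and ``t_drop`` are retained for diagnostics.
    """

    x: np.ndarray
    z: np.ndarray
    t_event: np.ndarray
    t_drop: np.ndarray
    time: np.ndarray
    event: np.ndarray

    @property
    def n(self) -> int:
        return self.time.shape[0]


def _half_split(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """(reps, n) arm indicators: exact half-split, shuffled per replicate."""
    n_control = (n + 1) // 2
    base = np.concatenate([np.zeros(n_control), np.ones(n - n_control)])
    u = rng.random((reps, n))
    order = np.argsort(u, axis=1)
    return np.take(base, order)


def simulate_batch(calibrated: CalibratedScenario, n: int, reps: int,
                   rng: np.random.Generator, control_only: bool = False,
                   x: np.ndarray | None = None):
    """Simulate ``reps`` independent cohorts of ``n`` patients.

    Returns ``(x, z, t_event, t_drop, time, event)`` with leading axis
    ``reps``. ``x`` may be supplied (e.g. truncated for eligibility
    restriction); otherwise it is drawn iid standard Gaussian.
    """
    sc = calibrated.scenario
    if x is None:
        x = rng.standard_normal((reps, n))
    if control_only:
        z = np.zeros((reps, n))
    else:
        z = _half_split(n, reps, rng)
    logh = np.clip(np.log(sc.theta) * z + calibrated.kappa
                   + calibrated.beta * x, -_CLIP, _CLIP)
    e = rng.exponential(1.0, (reps, n))
    t_event = (e / np.exp(logh)) ** (1.0 / sc.w)
    if sc.d > 0:
        t_drop = rng.exponential(1.0 / sc.d, (reps, n))
    else:
        t_drop = np.full((reps, n), np.inf)
    time = np.minimum(np.minimum(t_event, t_drop), sc.followup)
    event = t_event <= np.minimum(t_drop, sc.followup)
    return x, z, t_event, t_drop, time, event


def simulate_cohort(calibrated: CalibratedScenario, n: int,
                    rng: np.random.Generator,
                    control_only: bool = False) -> Cohort:
    """Simulate a single trial cohort (see module docstring for the model)."""
    if n < 4:
        raise ValueError("n must be at least 4")
    x, z, t_event, t_drop, time, event = simulate_batch(
        calibrated, n, 1, rng, control_only=control_only)
    return Cohort(x=x[0][:, None], z=z[0], t_event=t_event[0],
                  t_drop=t_drop[0], time=time[0], event=event[0])


def cohort_to_frame(cohort: Cohort):
    """Cohort as a tidy DataFrame with columns x, z, time, event."""
    import pandas as pd

    return pd.DataFrame({
        "x": cohort.x[:, 0], "z": cohort.z.astype(int),
        "time": cohort.time, "event": cohort.event.astype(int),
    })
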