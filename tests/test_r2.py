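"""Survival R2 measures: defining formulas, oracles and null behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covadjust.calibration import calibrate
from covadjust.r2 import (MEASURES, average_r2_panel, fleiss_predict,
                          r2_cox_snell, r2_panel)
from covadjust.scenarios import TrialScenario
from covadjust.simulate import simulate_cohort


def test_cox_snell_direct_values():
    assert r2_cox_snell(-100.0, -100.0, 50) == 0.0
    # likelihood gap of n/2 gives 1 - 1/e
    assert r2_cox_snell(0.0, 25.0, 50) == pytest.approx(1 - math.exp(-1),
                                                        abs=1e-12)
    with pytest.raises(ValueError):
        r2_cox_snell(-10.0, -20.0, 50)
    with pytest.raises(ValueError):
        r2_cox_snell(0.0, 1.0, 0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=50.0),
       st.floats(min_value=0.1, max_value=50.0))
def test_cox_snell_monotone_in_gap(gap, extra):
    n = 100
    assert r2_cox_snell(0.0, gap + extra, n) > r2_cox_snell(0.0, gap, n)


def test_fleiss_worked_values():
    assert fleiss_predict(1000, 0.25) == 750
    assert fleiss_predict(760, 0.0) == 760
    assert fleiss_predict(101, 0.5) == 52  # rounded up to even
    with pytest.raises(ValueError):
        fleiss_predict(100, 1.0)
    with pytest.raises(ValueError):
        fleiss_predict(100, -0.1)


def test_cox_snell_matches_independent_lifelines_fits():
    """Same formula computed from lifelines' likelihood-ratio statistic.

    lifelines provides 2*(l1 - l0) directly as the LR test statistic of
    a fitted Cox model, an implementation-independent oracle.
    """
    from lifelines import CoxPHFitter
    from covadjust.simulate import cohort_to_frame
    sc = TrialScenario(theta=0.7, w=1.5, d=0.0, Lambda_target=0.9,
                       C_target=0.75)
    cal = calibrate(sc)
    cohort = simulate_cohort(cal, 1000, np.random.default_rng(13),
                             control_only=True)
    panel = r2_panel(cohort)
    df = cohort_to_frame(cohort)[["x", "time", "event"]]
    cph = CoxPHFitter().fit(df, "time", "event")
    stat = cph.log_likelihood_ratio_test().test_statistic
    oracle = 1.0 - math.exp(-stat / len(df))
    assert panel.r2_cs == pytest.approx(oracle, abs=1e-6)
    # shared-formula algebra: fewer events inflate the per-event version
    assert panel.rho2_k >= panel.r2_cs


def test_km_weights_match_lifelines():
    """Event-time pmf used in rho2_XOQ agrees with lifelines' KM curve."""
    from lifelines import KaplanMeierFitter
    from covadjust.cox import _EfronWorkspace
    from covadjust.r2 import _km_event_weights
    rng = np.random.default_rng(4)
    n = 300
    t = rng.exponential(1.0, n)
    c = rng.exponential(1.5, n)
    time, ev = np.minimum(t, c), t <= c
    ws = _EfronWorkspace(time[None], ev[None], np.zeros((1, n, 0)))
    w = _km_event_weights(ws.t, ws.e)[0]
    km = KaplanMeierFitter().fit(time, ev)
    surv = km.survival_function_["KM_estimate"].to_numpy()
    jumps = -np.diff(np.concatenate([[1.0], surv]))
    jumps = jumps[jumps > 0]
    ours = np.sort(w[w > 0])[::-1]
    theirs = np.sort(jumps / jumps.sum())[::-1]
    assert np.allclose(ours, theirs, atol=1e-10)


def test_affine_invariance(cal_high_incidence):
    cohort = simulate_cohort(cal_high_incidence, 600,
                             np.random.default_rng(21), control_only=True)
    base = r2_panel(cohort)
    import copy
    scaled = copy.deepcopy(cohort)
    scaled.x = 3.0 * scaled.x - 7.0
    other = r2_panel(scaled)
    for m in MEASURES:
        assert getattr(base, m) == pytest.approx(getattr(other, m), abs=1e-7)


def test_null_covariate_measures_near_zero(cal_null_covariate):
    """Every measure's mean over 200 null datasets stays below small bias."""
    panel = average_r2_panel(cal_null_covariate,
                             np.random.default_rng(77), reps=200, n=1000)
    for m in MEASURES:
        assert 0.0 <= getattr(panel, m) <= 0.01


def test_panel_requires_events():
    import pandas as pd
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.1, 0.2]})
    with pytest.raises(ValueError):
        r2_panel(df, ["x"])
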