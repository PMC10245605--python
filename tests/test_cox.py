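"""Cox engine checks against hand enumeration and lifelines."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from covadjust.cox import (breslow_baseline, cox_wald_test, fit_cox,
                           fit_cox_batch)
from covadjust.simulate import Cohort


def _loglik_by_enumeration(time, event, X, beta):
    """Brute-force log partial likelihood (Breslow, loop over risk sets)."""
    eta = X @ beta
    ll = 0.0
    for i in np.where(event)[0]:
        risk = time >= time[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


def test_four_patient_hand_enumerated_risk_sets():
    """Log partial likelihood and score at beta=0 match risk-set enumeration."""
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([True, True, True, False])
    z = np.array([1.0, 0.0, 1.0, 0.0])
    res = fit_cox(time, event, z[:, None])
    # null log-likelihood: risk sets of sizes 4, 3, 2
    assert res.loglik_null == pytest.approx(-np.log(24.0), abs=1e-12)
    assert res.loglik_null == pytest.approx(
        _loglik_by_enumeration(time, event, z[:, None], np.zeros(1)))
    # score at 0 by central difference of the enumerated likelihood
    h = 1e-6
    score0 = (_loglik_by_enumeration(time, event, z[:, None], np.array([h]))
              - _loglik_by_enumeration(time, event, z[:, None],
                                       np.array([-h]))) / (2 * h)
    assert score0 == pytest.approx(1 / 2 - 1 / 3 + 1 / 2, abs=1e-6)
    # the fitted coefficient maximizes the enumerated likelihood
    assert res.loglik == pytest.approx(
        _loglik_by_enumeration(time, event, z[:, None], res.coef), abs=1e-9)
    grad = (_loglik_by_enumeration(time, event, z[:, None], res.coef + h)
            - _loglik_by_enumeration(time, event, z[:, None],
                                     res.coef - h)) / (2 * h)
    assert abs(grad) < 1e-4


@pytest.mark.parametrize("tied", [False, True])
def test_matches_lifelines(tied):
    """Coefficients, SEs and log-likelihood agree with lifelines (Efron)."""
    rng = np.random.default_rng(7)
    n = 250
    x = rng.standard_normal((n, 2))
    t = rng.exponential(1.0 / np.exp(0.6 * x[:, 0] - 0.4 * x[:, 1]))
    if tied:
        t = np.round(t, 1) + 0.05
    c = rng.exponential(2.0, n)
    time, ev = np.minimum(t, c), t <= c
    df = pd.DataFrame({"t": time, "e": ev.astype(int),
                       "x0": x[:, 0], "x1": x[:, 1]})
    cph = CoxPHFitter().fit(df, "t", "e")
    res = fit_cox(time, ev, x)
    assert np.allclose(res.coef, cph.params_.values, atol=2e-5)
    assert np.allclose(res.se, cph.standard_errors_.values, atol=2e-5)
    assert res.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_batch_consistent_with_single_fits():
    rng = np.random.default_rng(3)
    R, n = 20, 150
    x = rng.standard_normal((R, n))
    t = rng.exponential(1.0 / np.exp(0.5 * x))
    ev = t < 2.0
    tm = np.minimum(t, 2.0)
    batch = fit_cox_batch(tm, ev, x[..., None])
    for i in [0, 7, 19]:
        single = fit_cox(tm[i], ev[i], x[i][:, None])
        assert batch["beta"][i, 0] == pytest.approx(single.coef[0], abs=1e-9)


def test_wald_sign_and_magnitude_for_effective_treatment(cal_high_incidence):
    """A theta=0.7 effect at large n gives a clearly negative z-score."""
    from covadjust.simulate import simulate_cohort
    cohort = simulate_cohort(cal_high_incidence, 4000,
                             np.random.default_rng(11))
    res = cox_wald_test(cohort, adjust=True)
    assert res.treatment_coef < 0
    assert res.wald_z < -4
    unadj = cox_wald_test(cohort, adjust=False)
    assert unadj.names == ("treatment",)
    assert unadj.coef.shape == (1,)


def test_breslow_toy_increments():
    """Baseline hazard increments are 1/sum(risk) at each event time."""
    t = np.array([1.0, 2.0])
    e = np.array([True, True])
    times, H0 = breslow_baseline(t, e, np.zeros((2, 0)), np.zeros(0))
    assert np.allclose(times, [1.0, 2.0])
    assert np.allclose(H0, [0.5, 1.5])


def test_too_few_events_raises():
    with pytest.raises(ValueError):
        fit_cox(np.array([1.0, 2.0]), np.array([False, False]),
                np.ones((2, 1)))
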