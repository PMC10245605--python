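"""Surrogate cohort generation and Cox-model-based trial simulation."""

import numpy as np
import pandas as pd
import pytest

from covadjust.semisynthetic import (CLINICAL_COVARIATES, SCORE_COVARIATE,
                                     FittedCoxModel, design_matrix,
                                     eligibility_masks,
                                     fit_cox_with_baseline,
                                     generate_surrogate_cohort,
                                     simulate_from_fitted,
                                     simulate_from_fitted_batch)


def test_default_cohort_size_and_completeness(surrogate_table):
    assert len(surrogate_table) == 328
    assert not surrogate_table.isna().any().any()
    assert (surrogate_table["observed_time"] > 0).all()
    assert set(surrogate_table["tumor_staging"].unique()) <= {1, 2, 3}


def test_surrogate_large_sample_hits_calibration_targets():
    """At n=1e5 the generated cohort reproduces the published summaries."""
    from lifelines import KaplanMeierFitter
    rng = np.random.default_rng(123)
    tab = generate_surrogate_cohort(100_000, rng)
    masks = eligibility_masks(tab)
    assert masks["mildly_restrictive"].mean() == pytest.approx(0.82, abs=0.02)
    assert masks["most_restrictive"].mean() == pytest.approx(0.52, abs=0.02)
    km = KaplanMeierFitter().fit(tab["observed_time"], tab["event"])
    incidence_5y = 1.0 - float(km.survival_function_at_times(5.0).iloc[0])
    assert incidence_5y == pytest.approx(0.49, abs=0.02)


def test_fitted_c_indices_clinical_and_full():
    """Harrell's C of the fitted models: ~0.65 clinical, ~0.70 with score."""
    from lifelines.utils import concordance_index
    tab = generate_surrogate_cohort(20_000, np.random.default_rng(7))
    m_clin = fit_cox_with_baseline(tab, CLINICAL_COVARIATES)
    m_full = fit_cox_with_baseline(tab, CLINICAL_COVARIATES
                                   + (SCORE_COVARIATE,))
    lp_c = design_matrix(tab, m_clin.covariates) @ m_clin.coef
    lp_f = design_matrix(tab, m_full.covariates) @ m_full.coef
    t, e = tab["observed_time"], tab["event"]
    assert concordance_index(t, -lp_c, e) == pytest.approx(0.65, abs=0.02)
    assert concordance_index(t, -lp_f, e) == pytest.approx(0.70, abs=0.02)


def test_zero_score_coefficient_collapses_c_indices():
    from lifelines.utils import concordance_index
    tab = generate_surrogate_cohort(20_000, np.random.default_rng(8),
                                    score_coefficient=0.0)
    m_full = fit_cox_with_baseline(tab, CLINICAL_COVARIATES
                                   + (SCORE_COVARIATE,))
    lp_clin_part = design_matrix(tab, CLINICAL_COVARIATES) \
        @ m_full.coef[:len(CLINICAL_COVARIATES)]
    lp_f = design_matrix(tab, m_full.covariates) @ m_full.coef
    t, e = tab["observed_time"], tab["event"]
    c_f = concordance_index(t, -lp_f, e)
    c_c = concordance_index(t, -lp_clin_part, e)
    assert c_f == pytest.approx(c_c, abs=0.01)


def test_baseline_invariants_and_collinearity(surrogate_table):
    model = fit_cox_with_baseline(surrogate_table, CLINICAL_COVARIATES)
    s = model.baseline_survival
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s > 0) & (s <= 1.0))
    dup = surrogate_table.assign(dup=surrogate_table["risk_score"])
    with pytest.raises(ValueError, match="collinear"):
        fit_cox_with_baseline(dup, ("risk_score", "dup"))


def test_parameter_recovery_at_n5000(surrogate_table):
    """Fit on data simulated from a fitted model recovers coefficients."""
    from covadjust.cox import fit_cox
    model = fit_cox_with_baseline(surrogate_table,
                                  CLINICAL_COVARIATES + (SCORE_COVARIATE,))
    rng = np.random.default_rng(10)
    Xd, z, time, event, _ = simulate_from_fitted_batch(
        model, surrogate_table, theta=1.0, n=5000, reps=1, rng=rng)
    refit = fit_cox(time[0], event[0], Xd[0, :, 1:])
    for j in range(len(model.coef)):
        assert refit.coef[j] == pytest.approx(model.coef[j],
                                              abs=3 * refit.se[j])


def test_identity_hazard_reproduces_baseline(surrogate_table):
    """With h=1 the simulated KM curve tracks S0 (sup distance < 0.02)."""
    from lifelines import KaplanMeierFitter
    model = fit_cox_with_baseline(surrogate_table, CLINICAL_COVARIATES)
    null_model = FittedCoxModel(
        covariates=(), coef=np.empty(0),
        baseline_times=model.baseline_times,
        baseline_survival=model.baseline_survival,
        loglik=0.0, loglik_null=0.0)
    rng = np.random.default_rng(11)
    _, _, time, event, _ = simulate_from_fitted_batch(
        null_model, surrogate_table, theta=1.0, n=100_000, reps=1, rng=rng,
        followup=5.0)
    km = KaplanMeierFitter().fit(time[0], event[0])
    grid = model.baseline_times[model.baseline_times <= 4.9]
    km_vals = km.survival_function_at_times(grid).to_numpy()
    s0_vals = np.interp(grid, model.baseline_times, model.baseline_survival)
    assert np.max(np.abs(km_vals - s0_vals)) < 0.02


def test_high_risk_profile_powers_the_baseline(surrogate_table):
    """A profile with h=3 follows S0(t)^3 pointwise within MC error."""
    model = fit_cox_with_baseline(surrogate_table, CLINICAL_COVARIATES)
    const = pd.DataFrame({"c": np.ones(4)})
    model3 = FittedCoxModel(
        covariates=("c",), coef=np.array([np.log(3.0)]),
        baseline_times=model.baseline_times,
        baseline_survival=model.baseline_survival,
        loglik=0.0, loglik_null=0.0)
    rng = np.random.default_rng(12)
    _, _, time, event, _ = simulate_from_fitted_batch(
        model3, const, theta=1.0, n=100_000, reps=1, rng=rng,
        stratify_on=None, followup=5.0)
    grid = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
    s0_cubed = np.interp(grid, model.baseline_times,
                         model.baseline_survival) ** 3
    # survival at grid times (simulated times lie on the baseline support)
    emp_surv = [((time[0] > g) | ((time[0] >= g) & ~event[0])).mean()
                for g in grid]
    assert np.allclose(emp_surv, s0_cubed, atol=0.02)


def test_administrative_censoring_bounds_times(surrogate_table):
    model = fit_cox_with_baseline(surrogate_table,
                                  CLINICAL_COVARIATES + (SCORE_COVARIATE,))
    cohort = simulate_from_fitted(model, surrogate_table, 0.72, 760,
                                  np.random.default_rng(13))
    assert (cohort.time <= 5.0).all()
    assert (cohort.time > 0).all()


def test_stratified_randomization_balances_within_strata(surrogate_table):
    model = fit_cox_with_baseline(surrogate_table, CLINICAL_COVARIATES)
    rng = np.random.default_rng(14)
    Xd, z, _, _, rows = simulate_from_fitted_batch(
        model, surrogate_table, 0.72, 761, 5, rng)
    stages = surrogate_table["tumor_staging"].to_numpy()
    for r in range(5):
        strata = stages[rows[r]]
        for s in np.unique(strata):
            arm = z[r][strata == s]
            assert abs(arm.sum() - (len(arm) - arm.sum())) <= 1
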