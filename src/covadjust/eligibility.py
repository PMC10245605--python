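"""Eligibility-broadening experiments: power versus number of events.

Restricting a trial to lower-risk patients lowers the event rate, so
comparisons between eligibility designs are made at matched *numbers of
events* rather than matched sample sizes. For parametric simulations the
restricted design enrolls only patients whose prognostic covariate lies
below the 80% population quantile of the standard Gaussian (enrollment
continues until the target randomized n is reached, so the restricted
trial has full n with a truncated covariate distribution). For
semi-synthetic simulations the three nested eligibility levels of the
HCC cohort are used, and the most restrictive level drops ECOG from the
adjustment set because it is constant there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .power import _pvalues_pair
from .scenarios import CalibratedScenario
from .simulate import Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EligibilityRule:
    """A named inclusion rule; lower ``level`` = more restrictive."""

    name: str
    predicate: Callable[[pd.DataFrame], np.ndarray]
    level: int


def truncated_gauss_sampler(quantile: float):
    """Sampler of x | x < Phi^-1(quantile) for restricted enrollment.

    Uses the population (not sample) quantile of the standard Gaussian;
    inverse-CDF sampling keeps the stream reproducible.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")

    def sampler(reps: int, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random((reps, n))
        return stats.norm.ppf(u * quantile)

    return sampler


def restrict_parametric(cohort: Cohort, quantile: float = 0.8) -> Cohort:
    """Subset a cohort to patients with x below the population quantile."""
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    keep = cohort.x[:, 0] < stats.norm.ppf(quantile)
    return Cohort(x=cohort.x[keep], z=cohort.z[keep],
                  t_event=cohort.t_event[keep], t_drop=cohort.t_drop[keep],
                  time=cohort.time[keep], event=cohort.event[keep])


def screened_population(n_required: int, inclusion_fraction: float) -> int:
    """Patients to screen so that ``n_required`` are enrolled (expectation)."""
    if not (0.0 < inclusion_fraction <= 1.0):
        raise ValueError("inclusion_fraction must be in (0, 1]")
    return int(math.ceil(n_required / inclusion_fraction))


def run_eligibility_experiment(calibrated: CalibratedScenario,
                               n_grid, reps: int = 10_000,
                               seed: int = 11,
                               quantile: float = 0.8) -> pd.DataFrame:
    """Parametric 2 eligibility x 2 adjustment power table over ``n_grid``.

    The scenario must be calibrated on the *broad* population; the
    restricted design truncates the covariate below the population
    ``quantile``. Both analyses share each replicate cohort, and both
    eligibility designs share the master seed, so contrasts are paired.
    """
    rows = []
    sampler = truncated_gauss_sampler(quantile)
    alpha = calibrated.scenario.alpha
    for n in n_grid:
        for elig, xs in (("broad", None), ("restricted", sampler)):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(n)]))
            pu, pa, mean_events, _ = _pvalues_pair(
                calibrated, int(n), reps, rng, x_sampler=xs)
            for adjusted, p in ((False, pu), (True, pa)):
                power = float((p < alpha).mean())
                rows.append((elig, adjusted, int(n), mean_events, power,
                             math.sqrt(power * (1 - power) / reps)))
    return pd.DataFrame(rows, columns=["eligibility", "adjusted", "n",
                                       "mean_events", "power", "mc_se"])


def run_eligibility_experiment_semisynthetic(table: pd.DataFrame,
                                             n_grid, theta: float = 0.72,
                                             reps: int = 10_000,
                                             seed: int = 11) -> pd.DataFrame:
    """Semi-synthetic 3 eligibility x 2 adjustment power table.

    The generative model is fitted once on the full cohort; each
    eligibility level resamples covariate rows from its eligible subset.
    Covariates that are constant within a level (ECOG at the most
    restrictive level) are dropped from the adjustment set with a logged
    warning.
    """
    from .cox import batch_wald_pvalues
    from .semisynthetic import (CLINICAL_COVARIATES, SCORE_COVARIATE,
                                eligibility_masks, fit_cox_with_baseline,
                                simulate_from_fitted_batch)

    model = fit_cox_with_baseline(table,
                                  CLINICAL_COVARIATES + (SCORE_COVARIATE,))
    masks = eligibility_masks(table)
    alpha = 0.05
    rows = []
    for lev_idx, (level, mask) in enumerate(masks.items()):
        sub = table.loc[mask].reset_index(drop=True)
        # identify covariate columns constant on this subpopulation
        keep = [0]  # treatment
        names = list(model.covariates)
        for j, name in enumerate(names):
            from .semisynthetic import design_matrix
            col = design_matrix(sub, [name])[:, 0]
            if np.ptp(col) == 0:
                logger.warning("dropping constant covariate %r for level %s",
                               name, level)
            else:
                keep.append(j + 1)
        keep_clin = [j for j in keep if j == 0
                     or names[j - 1] != SCORE_COVARIATE]
        for n in n_grid:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(n), lev_idx]))
            chunk = max(32, int(2_000_000 / int(n)))
            pc, ps, ev = [], [], 0.0
            done = 0
            while done < reps:
                r = min(chunk, reps - done)
                Xd, _, time, event, _ = simulate_from_fitted_batch(
                    model, sub, theta, int(n), r, rng)
                p1, _ = batch_wald_pvalues(time, event, Xd[:, :, keep_clin])
                p2, _ = batch_wald_pvalues(time, event, Xd[:, :, keep])
                pc.append(p1)
                ps.append(p2)
                ev += float(event.sum())
                done += r
            for adjusted, p in ((False, np.concatenate(pc)),
                                (True, np.concatenate(ps))):
                power = float((p < alpha).mean())
                rows.append((level, adjusted, int(n), ev / reps, power,
                             math.sqrt(power * (1 - power) / reps)))
    return pd.DataFrame(rows, columns=["eligibility", "adjusted", "n",
                                       "mean_events", "power", "mc_se"])


def power_at_matched_events(table: pd.DataFrame, eligibility: str,
                            adjusted: bool, events_grid) -> np.ndarray:
    """Interpolate a scenario's power-vs-mean-events curve on a grid."""
    sub = table[(table.eligibility == eligibility)
                & (table.adjusted == adjusted)].sort_values("mean_events")
    return np.interp(np.asarray(events_grid, dtype=float),
                     sub["mean_events"], sub["power"])
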