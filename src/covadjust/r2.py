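"""Survival R-squared measures and the generalized Fleiss prediction.

Eight proportion-like summaries of a Cox model's prognostic strength are
computed side by side, spanning the two families used in the explained
variation / explained randomness literature:

Explained randomness (likelihood/entropy based)
    * ``r2_cs``   Cox-Snell: 1 - exp(-(2/n)(l1 - l0)) from the partial
      log-likelihoods of the covariate model (l1) and the null model (l0).
    * ``rho2_k``  the same with n replaced by the event count k.
    * ``rho2_xoq`` Xu-O'Quigley explained randomness 1 - exp(-Gamma),
      where Gamma doubles the average conditional information gain over
      event times, weighted by the Kaplan-Meier estimate of the marginal
      event-time distribution (reduces to ``rho2_k`` without censoring).
    * ``rho2_wa`` Kent-O'Quigley Weibull-approximation v / (v + 1), with
      v the variance of the fitted prognostic index.

Explained variation (variance of the prognostic index PI = X beta-hat)
    * ``r2_pm``   v / (v + pi^2/6), the PH analogue of the proportion of
      variance on the log-time scale (pi^2/6 is the extreme-value
      residual variance).
    * ``r2_d``    Royston-Sauerbrei D-based measure: D is the Cox
      coefficient of the scaled normal order statistics (Blom rankits
      divided by kappa = sqrt(8/pi)) substituted for the PI ranks;
      R2_D = (D^2/kappa^2) / (D^2/kappa^2 + pi^2/6).
    * ``r2_i``    variant of ``r2_d`` with unit (exponential) residual
      variance: (D^2/kappa^2) / (D^2/kappa^2 + 1).
    * ``r2_r``    robust variant of ``r2_pm`` with the PI variance
      estimated from the interquartile range (IQR/1.349)^2.

All measures are invariant to affine rescaling of the covariates (the
Cox fit absorbs scale) and approach 0 for a non-prognostic covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import fit_cox_batch
from .scenarios import CalibratedScenario
from .simulate import Cohort, simulate_batch

_PI2_6 = math.pi ** 2 / 6.0
_KAPPA = math.sqrt(8.0 / math.pi)

MEASURES = ("r2_cs", "rho2_k", "r2_d", "r2_i", "r2_pm", "r2_r",
            "rho2_wa", "rho2_xoq")


@dataclass
class R2Panel:
    """The eight measures plus the fit bookkeeping they derive from."""

    r2_cs: float
    rho2_k: float
    r2_d: float
    r2_i: float
    r2_pm: float
    r2_r: float
    rho2_wa: float
    rho2_xoq: float
    n: int
    k: float
    loglik_base: float
    loglik_full: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


def r2_cox_snell(l0: float, l1: float, n: int) -> float:
    """Cox-Snell R2 from nested log-likelihoods: 1 - exp(-(2/n)(l1-l0))."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if l1 < l0 - 1e-6:
        raise ValueError(f"nesting violated: l1={l1} < l0={l0}")
    return 1.0 - math.exp(-2.0 * max(l1 - l0, 0.0) / n)


def fleiss_predict(n0: int, r2: float) -> int:
    """Adjusted-analysis sample size N0 * (1 - r2), rounded up to even."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if n0 < 1:
        raise ValueError("n0 must be at least 1")
    n = n0 * (1.0 - r2)
    return int(2 * math.ceil(n / 2.0))


def _km_event_weights(time_sorted, event_sorted):
    """KM-based event-time pmf weights, per replicate (no tied events).

    ``time_sorted``/``event_sorted`` are (R, n), ascending, events first
    among ties. Returns (R, n) weights, zero at censored positions,
    normalized to sum to one over the events of each replicate.
    """
    R, n = time_sorted.shape
    at_risk = np.arange(n, 0, -1, dtype=np.float64)
    ef = event_sorted.astype(np.float64)
    factors = 1.0 - ef / at_risk
    surv_after = np.cumprod(factors, axis=1)
    surv_before = np.concatenate(
        [np.ones((R, 1)), surv_after[:, :-1]], axis=1)
    df = ef * surv_before / at_risk
    tot = df.sum(axis=1, keepdims=True)
    return df / np.where(tot > 0, tot, 1.0)


def _panel_batch(time, event, X):
    """All eight measures for each replicate dataset; returns dict of (R,)."""
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, dtype=np.float64)
    R, n, p = X.shape
    fit = fit_cox_batch(time, event, X)
    ll1, ll0, k = fit["loglik"], fit["loglik_null"], fit["n_events"]
    gap = np.maximum(ll1 - ll0, 0.0)
    r2_cs = 1.0 - np.exp(-2.0 * gap / n)
    rho2_k = 1.0 - np.exp(-2.0 * gap / np.maximum(k, 1.0))

    pi_index = np.einsum("rnp,rp->rn", X, fit["beta"])
    v = pi_index.var(axis=1, ddof=1)
    r2_pm = v / (v + _PI2_6)
    rho2_wa = v / (v + 1.0)
    q25, q75 = np.percentile(pi_index, [25, 75], axis=1)
    vq = ((q75 - q25) / 1.349) ** 2
    r2_r = vq / (vq + _PI2_6)

    # Royston-Sauerbrei D: Cox regression on scaled normal order statistics
    ranks = np.argsort(np.argsort(pi_index, axis=1), axis=1)
    rankits = stats.norm.ppf((np.arange(1, n + 1) - 3.0 / 8.0) / (n + 0.25))
    q = np.take(rankits, ranks) / _KAPPA
    dfit = fit_cox_batch(time, event, q[..., None])
    D = dfit["beta"][:, 0]
    d2k2 = (D / _KAPPA) ** 2
    r2_d = d2k2 / (d2k2 + _PI2_6)
    r2_i = d2k2 / (d2k2 + 1.0)

    # Xu-O'Quigley: KM-weighted average conditional information gain
    ws = fit["workspace"]
    eta_s = np.einsum("rnp,rp->rn", ws.X, fit["beta"])
    den_full = np.exp(eta_s)[:, ::-1].cumsum(axis=1)[:, ::-1]
    den_null = np.arange(n, 0, -1, dtype=np.float64)
    lr = eta_s - np.log(den_full) + np.log(den_null)
    wkm = _km_event_weights(ws.t, ws.e)
    gamma = 2.0 * (wkm * lr).sum(axis=1)
    rho2_xoq = 1.0 - np.exp(-np.maximum(gamma, 0.0))

    return {"r2_cs": r2_cs, "rho2_k": rho2_k, "r2_d": r2_d, "r2_i": r2_i,
            "r2_pm": r2_pm, "r2_r": r2_r, "rho2_wa": rho2_wa,
            "rho2_xoq": rho2_xoq, "k": k.astype(float),
            "loglik_base": ll0, "loglik_full": ll1}


def r2_panel(data, covariates=None) -> R2Panel:
    """The eight-measure panel for one dataset.

    ``data`` is either a :class:`~covadjust.simulate.Cohort` (its
    covariate matrix is used) or a DataFrame with ``time`` and ``event``
    columns plus the named ``covariates``.
    """
    if isinstance(data, Cohort):
        time, event, X = data.time, data.event, data.x
    else:
        if not covariates:
            raise ValueError("covariates must be named for table input")
        time = data["time"].to_numpy(dtype=float)
        event = data["event"].to_numpy()
        X = data[list(covariates)].to_numpy(dtype=float)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    out = _panel_batch(time[None, :], event.astype(bool)[None, :],
                       np.asarray(X, dtype=float)[None, :, :])
    vals = {m: float(out[m][0]) for m in MEASURES}
    return R2Panel(**vals, n=len(time), k=float(out["k"][0]),
                   loglik_base=float(out["loglik_base"][0]),
                   loglik_full=float(out["loglik_full"][0]))


def average_r2_panel(calibrated: CalibratedScenario,
                     rng: np.random.Generator, reps: int = 1000,
                     n: int = 1000) -> R2Panel:
    """Mean panel over ``reps`` simulated control-arm datasets of size ``n``.

    Follows the measure-averaging protocol of the simulation study: each
    estimate is the average of per-dataset measures, each dataset holding
    control patients only, simulated (with drop-out and administrative
    censoring) from the calibrated scenario.
    """
    sums = {m: 0.0 for m in MEASURES}
    k_sum = l0_sum = l1_sum = 0.0
    chunk = max(16, int(2_000_000 / n))
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        x, _, _, _, time, event = simulate_batch(calibrated, n, r, rng,
                                                 control_only=True)
        out = _panel_batch(time, event, x[..., None])
        for m in MEASURES:
            sums[m] += float(out[m].sum())
        k_sum += float(out["k"].sum())
        l0_sum += float(out["loglik_base"].sum())
        l1_sum += float(out["loglik_full"].sum())
        done += r
    vals = {m: sums[m] / reps for m in MEASURES}
    return R2Panel(**vals, n=n, k=k_sum / reps,
                   loglik_base=l0_sum / reps, loglik_full=l1_sum / reps)
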