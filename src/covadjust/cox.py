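"""Cox proportional-hazards fitting, vectorized across Monte-Carlo replicates.

The power simulations fit tens of thousands of small Cox models (one or a
few covariates, a few hundred to a few thousand patients). To make that
tractable, :func:`fit_cox_batch` runs Newton-Raphson on the log partial
likelihood simultaneously for a whole batch of replicate datasets, using
the Efron approximation for tied event times. For continuous simulated
times ties have probability zero and Efron coincides with Breslow; ties do
arise in semi-synthetic simulations, where event times live on the
discrete support of a Breslow baseline estimate.

The single-dataset entry point :func:`cox_wald_test` wraps the same engine
and returns the Wald test for the treatment coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_CLIP = 700.0  # exponent clip: exp(700) is near the float64 overflow edge


# ---------------------------------------------------------------------------
# tied-group machinery (all arrays (R, n), sorted ascending in time, axis=1)
# ---------------------------------------------------------------------------

def _group_bounds(t_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and last index of each tied-time group, per replicate."""
    R, n = t_sorted.shape
    idx = np.arange(n)
    new = np.ones((R, n), dtype=bool)
    new[:, 1:] = t_sorted[:, 1:] != t_sorted[:, :-1]
    gstart = np.maximum.accumulate(np.where(new, idx, 0), axis=1)
    last = np.empty((R, n), dtype=bool)
    last[:, :-1] = new[:, 1:]
    last[:, -1] = True
    gend = np.flip(
        np.minimum.accumulate(np.flip(np.where(last, idx, n), axis=1), axis=1),
        axis=1,
    )
    return gstart, gend


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.flip(np.cumsum(np.flip(a, 1), 1), 1)


def _group_sum(a: np.ndarray, gstart: np.ndarray, gend: np.ndarray) -> np.ndarray:
    """Sum of ``a`` over each tied group, broadcast back to every position."""
    cs = np.cumsum(a, axis=1)
    pad = np.concatenate([np.zeros_like(cs[:, :1, ...]), cs], axis=1)
    extra = a.ndim - gstart.ndim
    gs = gstart.reshape(gstart.shape + (1,) * extra)
    ge = gend.reshape(gend.shape + (1,) * extra)
    gs = np.broadcast_to(gs, a.shape)
    ge = np.broadcast_to(ge, a.shape)
    return np.take_along_axis(pad, ge + 1, axis=1) - np.take_along_axis(pad, gs, axis=1)


def _take_start(a: np.ndarray, gstart: np.ndarray) -> np.ndarray:
    extra = a.ndim - gstart.ndim
    gs = np.broadcast_to(gstart.reshape(gstart.shape + (1,) * extra), a.shape)
    return np.take_along_axis(a, gs, axis=1)


def _rcs(a: np.ndarray) -> np.ndarray:
    """Reverse cumulative sum along axis 1 (risk-set sums for ascending sort)."""
    return a[:, ::-1].cumsum(axis=1)[:, ::-1]


class _EfronWorkspace:
    """Sorted data plus tie structure, shared across Newton iterations."""

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray):
        # sort ascending in time with events first among ties: a tie group
        # then lists its events before its censored members, so plain
        # reverse-cumulative risk sums are exact whenever no *events* tie.
        pre = np.argsort(~np.asarray(event, dtype=bool), axis=1, kind="stable")
        t_pre = np.take_along_axis(time, pre, 1)
        order2 = np.argsort(t_pre, axis=1, kind="stable")
        order = np.take_along_axis(pre, order2, 1)
        self.t = np.take_along_axis(time, order, 1)
        self.e = np.take_along_axis(event, order, 1).astype(bool)
        self.X = np.ascontiguousarray(np.take_along_axis(X, order[..., None], 1))
        # Efron correction is needed only when two events share a time
        self.tied = bool(((self.t[:, 1:] == self.t[:, :-1])
                          & self.e[:, 1:] & self.e[:, :-1]).any())
        if self.tied:
            self.gstart, self.gend = _group_bounds(self.t)
            ccs = np.cumsum(self.e, axis=1)
            pad = np.concatenate([np.zeros_like(ccs[:, :1]), ccs], axis=1)
            before = np.take_along_axis(pad, self.gstart, axis=1)
            # 0-based rank of each event among the tied events of its group
            erank = np.where(self.e, ccs - before - 1, 0)
            self.d = _group_sum(self.e.astype(np.float64), self.gstart, self.gend)
            with np.errstate(invalid="ignore", divide="ignore"):
                self.frac = np.where(self.e, erank / np.maximum(self.d, 1.0), 0.0)
        self.ef = self.e.astype(np.float64)
        self.n_events = self.ef.sum(axis=1)

    def null_loglik(self) -> np.ndarray:
        """Log partial likelihood of the empty (no-covariate) model."""
        R, n = self.t.shape
        if not self.tied:
            den0 = np.broadcast_to(np.arange(n, 0, -1, dtype=np.float64), (R, n))
        else:
            den0 = (n - self.gstart).astype(np.float64) - self.frac * self.d
        return -(self.ef * np.log(den0)).sum(axis=1)

    def evaluate(self, beta: np.ndarray):
        """Log partial likelihood, score and information at ``beta`` (R, p)."""
        X, e, ef = self.X, self.e, self.ef
        R, n, p = X.shape
        eta = (X @ beta[..., None])[..., 0]
        w = np.exp(np.clip(eta, -_CLIP, _CLIP))
        if not self.tied:
            den0 = _rcs(w)
            mu = np.empty_like(X)
            for j in range(p):
                mu[..., j] = _rcs(w * X[..., j]) / den0
            ll = (ef * (eta - np.log(den0))).sum(axis=1)
            score = np.einsum("rn,rnp->rp", ef, X - mu)
            info = np.empty((R, p, p))
            for i in range(p):
                for j in range(i, p):
                    Vij = _rcs(w * X[..., i] * X[..., j]) / den0 \
                        - mu[..., i] * mu[..., j]
                    info[:, i, j] = info[:, j, i] = (ef * Vij).sum(axis=1)
            return ll, score, info
        ew = w * ef
        den0 = _take_start(_rcs(w), self.gstart) \
            - self.frac * _group_sum(ew, self.gstart, self.gend)
        mu = np.empty_like(X)
        for j in range(p):
            mu[..., j] = (_take_start(_rcs(w * X[..., j]), self.gstart)
                          - self.frac * _group_sum(ew * X[..., j],
                                                   self.gstart, self.gend)) / den0
        ll = (ef * (eta - np.log(den0))).sum(axis=1)
        score = np.einsum("rn,rnp->rp", ef, X - mu)
        info = np.empty((R, p, p))
        for i in range(p):
            for j in range(i, p):
                xij = X[..., i] * X[..., j]
                den2 = _take_start(_rcs(w * xij), self.gstart) \
                    - self.frac * _group_sum(ew * xij, self.gstart, self.gend)
                Vij = den2 / den0 - mu[..., i] * mu[..., j]
                info[:, i, j] = info[:, j, i] = (ef * Vij).sum(axis=1)
        return ll, score, info


def _solve_newton(info: np.ndarray, score: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(info, score[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.einsum("rpq,rq->rp", np.linalg.pinv(info), score)


def fit_cox_batch(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-8,
    beta_init: np.ndarray | None = None,
):
    """Fit a Cox PH model to each replicate dataset in a batch.

    Parameters
    ----------
    time, event : (R, n) arrays
        Observed times and event indicators per replicate.
    X : (R, n, p) array
        Covariate matrices.

    Returns
    -------
    dict with keys ``beta`` (R, p), ``se`` (R, p), ``loglik`` (R,),
    ``loglik_null`` (R,), ``converged`` (R,), ``n_events`` (R,),
    ``info`` (R, p, p).
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event)
    X = np.asarray(X, dtype=np.float64)
    R, n, p = X.shape
    ws = _EfronWorkspace(time, event, X)
    ll_null = ws.null_loglik()
    if beta_init is not None and p > 0:
        beta = np.broadcast_to(np.asarray(beta_init, dtype=np.float64),
                               (R, p)).copy()
    else:
        beta = np.zeros((R, p))
    ll, score, info = ws.evaluate(beta)
    converged = np.zeros(R, dtype=bool)
    if p == 0 or n == 0:
        return {
            "beta": beta, "se": np.zeros((R, p)), "loglik": ll,
            "loglik_null": ll_null, "converged": np.ones(R, dtype=bool),
            "n_events": ws.n_events, "info": info, "workspace": ws,
        }
    for _ in range(max_iter):
        delta = _solve_newton(info, score)
        # damp huge steps (near-separation); partial likelihood is concave
        delta = np.clip(delta, -2.0, 2.0)
        delta = np.where(converged[:, None], 0.0, delta)
        beta = beta + delta
        newly = np.max(np.abs(delta), axis=1) < tol
        converged |= newly
        if converged.all():
            break
        ll, score, info = ws.evaluate(beta)
    ll, score, info = ws.evaluate(beta)
    # runaway coefficients signal monotone likelihood (separation)
    converged &= np.all(np.abs(beta) < 50.0, axis=1)
    converged &= ws.n_events >= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        var = np.einsum("rpp->rp", cov)
        se = np.sqrt(np.where(var > 0, var, np.nan))
    return {
        "beta": beta, "se": se, "loglik": ll, "loglik_null": ll_null,
        "converged": converged, "n_events": ws.n_events, "info": info,
        "workspace": ws,
    }


def batch_wald_pvalues(time, event, X, coef_index: int = 0):
    """Two-sided Wald p-values for one coefficient across a batch of fits.

    Returns ``(p, converged)``; non-converged replicates get ``p = 1``
    (counted as non-rejections by callers — conservative).
    """
    fit = fit_cox_batch(time, event, X)
    z = fit["beta"][:, coef_index] / fit["se"][:, coef_index]
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(fit["converged"] & np.isfinite(p), p, 1.0)
    return p, fit["converged"]


# ---------------------------------------------------------------------------
# single-dataset interface
# ---------------------------------------------------------------------------

@dataclass
class CoxFitResult:
    """Wald-test summary of a single Cox PH fit (Efron ties)."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    wald_z: float
    p_value: float
    loglik: float
    loglik_null: float
    converged: bool
    n_events: int
    ties: str = "efron"

    @property
    def treatment_coef(self) -> float:
        return float(self.coef[0])


def fit_cox(time, event, X, names=None) -> CoxFitResult:
    """Fit one Cox model; the Wald test reported is for the first column."""
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.ndim == 2 and X.shape[0] == time.shape[0]:
        pass
    else:
        X = X.T
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    fit = fit_cox_batch(time[None, :], event[None, :], X[None, :, :])
    coef = fit["beta"][0]
    se = fit["se"][0]
    z = float(coef[0] / se[0]) if se[0] > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    return CoxFitResult(
        names=tuple(names), coef=coef, se=se, wald_z=z, p_value=p,
        loglik=float(fit["loglik"][0]), loglik_null=float(fit["loglik_null"][0]),
        converged=bool(fit["converged"][0]), n_events=int(fit["n_events"][0]),
    )


def cox_wald_test(cohort, adjust: bool) -> CoxFitResult:
    """Wald test for the treatment coefficient in a Cox regression.

    ``adjust=False`` fits treatment only; ``adjust=True`` additionally
    includes the cohort's covariate column(s).
    """
    x = np.atleast_2d(cohort.x.T).T  # (n, q)
    cols = [cohort.z.astype(np.float64)]
    names = ["treatment"]
    if adjust:
        for j in range(x.shape[1]):
            cols.append(x[:, j])
            names.append(f"x{j}" if x.shape[1] > 1 else "x")
    X = np.column_stack(cols)
    return fit_cox(cohort.time, cohort.event, X, names=names)


def breslow_baseline(time, event, X, beta):
    """Breslow baseline cumulative hazard at the zero-covariate profile.

    Returns ``(times, H0)``: distinct event times (ascending) and the
    cumulative hazard, with increments ``d_j / sum_{risk} exp(x beta)``.
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, dtype=np.float64)
    eta = X @ np.asarray(beta, dtype=np.float64) if X.size else np.zeros_like(time)
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order], np.exp(np.clip(eta[order], -_CLIP, _CLIP))
    riskset = np.flip(np.cumsum(np.flip(w)))  # sum of w over {time >= t_i}
    ev_times = np.unique(t[e])
    increments = np.empty_like(ev_times)
    for j, tt in enumerate(ev_times):
        at = t == tt
        dj = int((at & e).sum())
        denom = riskset[np.searchsorted(t, tt, side="left")]
        increments[j] = dj / denom
    return ev_times, np.cumsum(increments)
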