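"""Monte-Carlo power estimation and sample-size search.

Power of the two-sided Wald test for the treatment coefficient is
estimated by simulating replicate trials and fitting Cox models with
(``adjust=True``) and without (``adjust=False``) the prognostic
covariate. The two analyses always see the *same* replicate cohorts
(paired design), so the power difference — and the derived sample-size
reduction — is a paired estimate with strongly reduced Monte-Carlo
noise.

The sample-size search locates the even ``n`` at which power reaches the
target: a coarse geometric bracket around an analytic initial guess
(Schoenfeld's event formula divided by the simulated event fraction),
bisection refinement, then monotone (isotonic-then-linear) interpolation
of the probed power curve. Probe seeds are keyed on ``(master seed, n)``
so results are independent of probing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import batch_wald_pvalues
from .scenarios import CalibratedScenario
from .simulate import simulate_batch


@dataclass
class PowerEstimate:
    """A Monte-Carlo power estimate at one sample size."""

    n: int
    power: float
    mc_se: float
    reps: int
    adjusted: bool
    mean_events: float
    n_nonconverged: int = 0


@dataclass
class PowerCurve:
    """Power estimates over a grid of sample sizes (one analysis)."""

    adjusted: bool
    points: list[PowerEstimate] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.points]).sort_values("n")


@dataclass
class SampleSizeResult:
    """Required sample sizes at target power and the observed reduction."""

    N0: int
    Nadj: int
    R2_obs: float
    probes: pd.DataFrame | None = None

    def __post_init__(self):
        if self.N0 < 4 or self.Nadj < 4:
            raise ValueError("sample sizes must be at least 4")


def sample_size_reduction(N0: float, Nadj: float) -> float:
    """Observed relative sample-size reduction ``1 - Nadj / N0``.

    May be negative if adjustment increased the requirement; not clipped.
    """
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    return 1.0 - Nadj / N0


def _pvalues_pair(calibrated, n, reps, rng, chunk=None, x_sampler=None):
    """Simulate ``reps`` cohorts of size ``n``; Wald p-values for both analyses.

    Returns (p_unadj, p_adj, mean_events, n_nonconv). The same cohorts feed
    both fits (paired estimates).
    """
    sc = calibrated.scenario
    if chunk is None:
        chunk = max(64, int(4_000_000 / max(n, 1)))
    warm_u = np.array([np.log(sc.theta)])
    warm_a = np.array([np.log(sc.theta), calibrated.beta])
    p_u, p_a, events, nonconv = [], [], 0.0, 0
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        x = x_sampler(r, n, rng) if x_sampler is not None else None
        x, z, _, _, time, event = simulate_batch(calibrated, n, r, rng, x=x)
        X = np.stack([z, x], axis=2)
        pu, cu = batch_wald_pvalues(time, event, X[:, :, :1], coef_index=0)
        # reuse per-replicate data for the adjusted fit (paired seeds)
        pa, ca = batch_wald_pvalues(time, event, X, coef_index=0)
        p_u.append(pu)
        p_a.append(pa)
        events += float(event.sum())
        nonconv += int((~cu).sum() + (~ca).sum())
        done += r
    return (np.concatenate(p_u), np.concatenate(p_a),
            events / reps, nonconv)


def estimate_power(calibrated: CalibratedScenario, n: int, reps: int,
                   adjust: bool, rng: np.random.Generator,
                   alpha: float | None = None,
                   x_sampler=None) -> PowerEstimate:
    """Estimate rejection probability of the Wald test at sample size ``n``."""
    if reps < 100:
        raise ValueError("reps must be at least 100")
    sc = calibrated.scenario
    alpha = sc.alpha if alpha is None else alpha
    pu, pa, mean_events, nonconv = _pvalues_pair(
        calibrated, n, reps, rng, x_sampler=x_sampler)
    p = pa if adjust else pu
    power = float((p < alpha).mean())
    return PowerEstimate(n=n, power=power,
                         mc_se=float(np.sqrt(power * (1 - power) / reps)),
                         reps=reps, adjusted=adjust, mean_events=mean_events,
                         n_nonconverged=nonconv)


def _pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: nondecreasing fit to y."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    blocks = [[i, i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i][1] = blocks[i + 1][1]
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty_like(y)
    for (a, b), v in zip(blocks, vals):
        out[a:b + 1] = v
    return out


def _interpolate_target(ns, powers, reps, target):
    """Isotonic-then-linear inversion of the power curve at ``target``."""
    order = np.argsort(ns)
    ns = np.asarray(ns, dtype=float)[order]
    pw = _pava(np.asarray(powers, dtype=float)[order],
               np.asarray(reps, dtype=float)[order])
    if target <= pw[0]:
        return ns[0]
    if target >= pw[-1]:
        return ns[-1]
    return float(np.interp(target, pw, ns))


def _even(x: float) -> int:
    return max(4, int(round(x / 2.0)) * 2)


def _initial_guess(calibrated, seed: int) -> int:
    """Schoenfeld events divided by the simulated per-patient event rate."""
    sc = calibrated.scenario
    za = stats.norm.ppf(1 - sc.alpha / 2)
    zb = stats.norm.ppf(sc.power_target)
    events_needed = 4.0 * (za + zb) ** 2 / np.log(sc.theta) ** 2
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999_983]))
    m = 50_000
    _, _, _, _, _, event = simulate_batch(calibrated, m, 1, rng)
    pe = max(float(event.mean()), 1e-4)
    return _even(events_needed / pe)


class _ProbeCache:
    """Power probes keyed by n; probe seeds keyed by (master seed, n)."""

    def __init__(self, calibrated, reps, seed, alpha, x_sampler=None):
        self.calibrated = calibrated
        self.reps = reps
        self.seed = seed
        self.alpha = alpha
        self.x_sampler = x_sampler
        self.cache: dict[int, tuple[float, float, float]] = {}

    def probe(self, n: int) -> tuple[float, float]:
        n = _even(n)
        if n not in self.cache:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, n]))
            pu, pa, ev, _ = _pvalues_pair(self.calibrated, n, self.reps, rng,
                                          x_sampler=self.x_sampler)
            self.cache[n] = (float((pu < self.alpha).mean()),
                             float((pa < self.alpha).mean()), ev)
        c = self.cache[n]
        return c[0], c[1]

    def frame(self) -> pd.DataFrame:
        rows = [(n, pu, pa, ev) for n, (pu, pa, ev) in
                sorted(self.cache.items())]
        return pd.DataFrame(rows, columns=["n", "power_unadjusted",
                                           "power_adjusted", "mean_events"])


def _search_curve(probes: _ProbeCache, which: int, target: float,
                  n_start: int, n_max: int, rel_width: float) -> float:
    """Bracket + bisection + isotonic interpolation for one power curve."""
    n = _even(n_start)
    probes.probe(n)
    get = lambda m: probes.probe(m)[which]
    lo = hi = n
    for _ in range(60):
        if get(lo) < target:
            break
        lo = _even(lo / 1.3)
        if lo <= 4:
            break
    else:
        raise RuntimeError("failed to bracket power target from below")
    for _ in range(60):
        if get(hi) >= target:
            break
        hi = _even(hi * 1.3)
        if hi > n_max:
            raise RuntimeError(
                f"power target {target} not reached below n_max={n_max}")
    # tighten to the closest straddling pair already probed
    ns = sorted(m for m in probes.cache if lo <= m <= hi)
    for m in ns:
        if probes.probe(m)[which] < target and m > lo:
            lo = m
        if probes.probe(m)[which] >= target and m < hi:
            hi = m
    while hi - lo > max(2, rel_width * hi):
        mid = _even((lo + hi) / 2)
        if mid in (lo, hi):
            break
        if get(mid) < target:
            lo = mid
        else:
            hi = mid
    ns = sorted(probes.cache)
    pw = [probes.probe(m)[which] for m in ns]
    return _interpolate_target(ns, pw, [probes.reps] * len(ns), target)


def find_sample_size(calibrated: CalibratedScenario, adjust: bool,
                     seed: int, reps: int = 2000, n_max: int = 200_000,
                     rel_width: float = 0.02) -> int:
    """Even sample size reaching the scenario's target power (one analysis)."""
    sc = calibrated.scenario
    probes = _ProbeCache(calibrated, reps, seed, sc.alpha)
    n0 = _initial_guess(calibrated, seed)
    which = 1 if adjust else 0
    start = n0 if adjust else _even(n0 * 1.05)
    n = _search_curve(probes, which, sc.power_target, start, n_max, rel_width)
    return _even(n)


def find_sample_sizes_paired(calibrated: CalibratedScenario, seed: int,
                             reps: int = 2000, n_max: int = 200_000,
                             rel_width: float = 0.02,
                             x_sampler=None) -> SampleSizeResult:
    """N0, Nadj and the observed reduction from one shared probe cache.

    Both analyses are evaluated on the same replicate cohorts at every
    probed n, so ``R2_obs = 1 - Nadj/N0`` is a paired estimate.
    """
    sc = calibrated.scenario
    probes = _ProbeCache(calibrated, reps, seed, sc.alpha,
                         x_sampler=x_sampler)
    n0_guess = _initial_guess(calibrated, seed)
    nadj = _search_curve(probes, 1, sc.power_target, n0_guess, n_max,
                         rel_width)
    n0 = _search_curve(probes, 0, sc.power_target,
                       max(_even(nadj * 1.1), n0_guess), n_max, rel_width)
    return SampleSizeResult(N0=_even(n0), Nadj=_even(nadj),
                            R2_obs=sample_size_reduction(n0, nadj),
                            probes=probes.frame())
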