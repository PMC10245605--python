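"""Cox-model-based (semi-synthetic) simulation from a cohort table.

The workflow mirrors trial simulation anchored on a real observational
cohort of resected hepatocellular-carcinoma (HCC) patients: a Cox model
of overall survival is fitted on the cohort's prognostic variables
(tumor staging, ECOG performance status, and a continuous prognostic
risk score), and simulated trials resample covariate rows from the
cohort, assign treatment 1:1 stratified on tumor staging, and draw event
times by inverting the fitted model's step-function survival curve
``S(t | z, X) = S0(t)^(theta^z * exp(beta'X))``. All patients with
events after 5 years are censored at that time.

Because the original cohort (resected-HCC patients with deep-learning
prognostic scores) is not publicly available,
:func:`generate_surrogate_cohort`
provides a synthetic stand-in: correlated clinical covariates and a
Gaussian latent risk score drawn from a single-factor Gaussian copula,
with the ground-truth hazard calibrated so that the cohort reproduces
the published summary targets — 5-year death incidence ~0.49, a
clinical-model concordance of ~0.65 rising to ~0.70 with the score, and
nested eligibility fractions of ~0.82 (mildly restrictive) and ~0.52
(most restrictive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cox import breslow_baseline, fit_cox, fit_cox_batch
from .simulate import Cohort

logger = logging.getLogger(__name__)

_CLIP = 700.0

COLUMN_DICTIONARY = {
    "tumor_staging": "ordered tumor stage: 1, 2, 3 (higher = more advanced)",
    "ecog": "ECOG performance status: 0, 1, 2 (higher = worse)",
    "child_pugh": "Child-Pugh class: 0 = A, 1 = B or worse",
    "macrovascular_invasion": "macrovascular invasion present (0/1)",
    "hbv": "hepatitis B infection (0/1)",
    "hcv": "hepatitis C infection (0/1)",
    "risk_score": "continuous prognostic score, higher = higher risk",
    "observed_time": "follow-up time in years (> 0)",
    "event": "death observed during follow-up (0/1)",
}

CLINICAL_COVARIATES = ("stage2", "stage3", "ecog1")
SCORE_COVARIATE = "risk_score"


@dataclass
class SurrogateConfig:
    """Marginals, dependence and calibration targets of the surrogate cohort.

    A single latent severity factor with per-variable loadings induces
    the correlation between covariates; ground-truth log-hazards are a
    fixed direction rescaled during calibration.
    """

    n_default: int = 328
    stage_probs: tuple[float, ...] = (0.55, 0.30, 0.15)
    ecog_probs: tuple[float, ...] = (0.62, 0.29, 0.09)  # recalibrated below
    p_child_pugh_b: float = 0.10
    p_mvi: float = 0.12
    p_hbv: float = 0.35
    p_hcv: float = 0.20
    loadings: dict = field(default_factory=lambda: {
        "tumor_staging": 0.55, "ecog": 0.45, "child_pugh": 0.40,
        "macrovascular_invasion": 0.45, "hbv": 0.10, "hcv": 0.10,
        "risk_score": 0.60,
    })
    # ground-truth log-hazard direction (rescaled in calibration)
    base_clinical: dict = field(default_factory=lambda: {
        "stage2": 0.5, "stage3": 1.0, "ecog1": 0.6})
    weibull_shape: float = 1.5
    followup: float = 5.0
    target_incidence: float = 0.49
    target_c_clinical: float = 0.65
    target_c_full: float = 0.70
    target_frac_mild: float = 0.82
    target_frac_most: float = 0.52
    calibration_n: int = 200_000
    calibration_seed: int = 20230606  # fixed: calibration is deterministic
    tol: float = 0.02


@dataclass
class SurrogateGroundTruth:
    """Calibrated latent thresholds and hazard coefficients."""

    config: SurrogateConfig
    ecog_cut0: float
    ecog_cut1: float
    scale_clinical: float
    scale_score: float
    kappa: float
    achieved: dict


@dataclass
class FittedCoxModel:
    """Cox coefficients plus a Breslow baseline survival step function.

    ``baseline_times`` / ``baseline_survival`` describe the
    right-continuous survival estimate at the zero-covariate profile
    ("null data point"): S0(t) = baseline_survival[j] for
    baseline_times[j] <= t < baseline_times[j+1], S0(t) = 1 before the
    first event time.
    """

    covariates: tuple[str, ...]
    coef: np.ndarray
    baseline_times: np.ndarray
    baseline_survival: np.ndarray
    loglik: float
    loglik_null: float

    def __post_init__(self):
        s = self.baseline_survival
        if len(s) and (np.any(np.diff(s) > 1e-12) or np.any(s <= 0)
                       or np.any(s > 1.0 + 1e-12)):
            raise ValueError("baseline survival must be non-increasing in (0,1]")


# ---------------------------------------------------------------------------
# surrogate cohort generation
# ---------------------------------------------------------------------------

def _thresholds(probs) -> np.ndarray:
    from scipy.stats import norm
    return norm.ppf(np.cumsum(probs)[:-1])


def _draw_latents(cfg: SurrogateConfig, n: int, rng: np.random.Generator):
    """Latent Gaussian variables of the single-factor copula."""
    sev = rng.standard_normal(n)
    lat = {}
    for name, lam in cfg.loadings.items():
        lat[name] = lam * sev + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
    return lat


def _covariates_from_latents(cfg, gt, lat) -> pd.DataFrame:
    from scipy.stats import norm
    st = _thresholds(cfg.stage_probs)
    stage = 1 + (lat["tumor_staging"] > st[0]).astype(int) \
        + (lat["tumor_staging"] > st[1]).astype(int)
    ecog = (lat["ecog"] > gt.ecog_cut0).astype(int) \
        + (lat["ecog"] > gt.ecog_cut1).astype(int)
    cp = (lat["child_pugh"] > norm.ppf(1 - cfg.p_child_pugh_b)).astype(int)
    mvi = (lat["macrovascular_invasion"] > norm.ppf(1 - cfg.p_mvi)).astype(int)
    hbv = (lat["hbv"] > norm.ppf(1 - cfg.p_hbv)).astype(int)
    hcv = (lat["hcv"] > norm.ppf(1 - cfg.p_hcv)).astype(int)
    return pd.DataFrame({
        "tumor_staging": stage, "ecog": ecog, "child_pugh": cp,
        "macrovascular_invasion": mvi, "hbv": hbv, "hcv": hcv,
        "risk_score": lat["risk_score"],
    })


def design_matrix(table: pd.DataFrame, covariates) -> np.ndarray:
    """Expand named covariates into a numeric design matrix.

    ``stage2``/``stage3`` are tumor-staging dummies, ``ecog1`` is the
    indicator of ECOG >= 1; any other name is taken as a numeric column.
    """
    cols = []
    for c in covariates:
        if c == "stage2":
            cols.append((table["tumor_staging"] == 2).astype(float))
        elif c == "stage3":
            cols.append((table["tumor_staging"] == 3).astype(float))
        elif c == "ecog1":
            cols.append((table["ecog"] >= 1).astype(float))
        else:
            cols.append(table[c].astype(float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def eligibility_masks(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Nested inclusion masks: less / mildly / most restrictive."""
    mild = (table["child_pugh"] == 0) & (table["ecog"] <= 1)
    most = mild & (table["ecog"] == 0) \
        & (table["macrovascular_invasion"] == 0) \
        & ~((table["hbv"] == 1) & (table["hcv"] == 1))
    return {"less_restrictive": np.ones(len(table), dtype=bool),
            "mildly_restrictive": mild.to_numpy(),
            "most_restrictive": most.to_numpy()}


def _true_linear_predictor(cfg, gt, table, clinical_only=False):
    X = design_matrix(table, CLINICAL_COVARIATES)
    base = np.array([cfg.base_clinical[c] for c in CLINICAL_COVARIATES])
    lp = gt.scale_clinical * (X @ base)
    if not clinical_only:
        lp = lp + gt.scale_score * table["risk_score"].to_numpy()
    return lp


def _pair_concordance(lp: np.ndarray, obs: np.ndarray, ev: np.ndarray,
                      i: np.ndarray, j: np.ndarray) -> float:
    """Harrell's C on censored data via fixed random pair subsampling.

    Tied predictions get the standard half credit (as in lifelines and
    R ``survival``) — with a discrete clinical linear predictor the tied
    mass is large, so the convention materially changes the value.
    """
    ti, tj = obs[i], obs[j]
    i_short = ti < tj
    usable = (i_short & ev[i]) | ((tj < ti) & ev[j])
    correct = np.where(i_short, lp[i] > lp[j], lp[j] > lp[i]).astype(float)
    credit = np.where(lp[i] == lp[j], 0.5, correct)
    return float(credit[usable].mean())


def calibrate_surrogate(cfg: SurrogateConfig | None = None,
                        max_rounds: int = 5) -> SurrogateGroundTruth:
    """Solve the surrogate generator's free parameters for its targets.

    Deterministic: uses a fixed internal latent sample (common random
    numbers), so repeated calls give bit-identical ground truth. Raises
    if any target is missed by more than ``cfg.tol`` after bounded
    alternating rounds.
    """
    from scipy.stats import norm
    cfg = cfg or SurrogateConfig()
    rng = np.random.default_rng(cfg.calibration_seed)
    n = cfg.calibration_n
    lat = _draw_latents(cfg, n, rng)
    expo = rng.exponential(1.0, n)
    cens = rng.uniform(1.0, 12.0, n)  # same censoring law as the generator
    pair_i = rng.integers(0, n, 2_000_000)
    pair_j = rng.integers(0, n, 2_000_000)

    cp_ok = lat["child_pugh"] <= norm.ppf(1 - cfg.p_child_pugh_b)
    mvi_ok = lat["macrovascular_invasion"] <= norm.ppf(1 - cfg.p_mvi)
    dual = (lat["hbv"] > norm.ppf(1 - cfg.p_hbv)) \
        & (lat["hcv"] > norm.ppf(1 - cfg.p_hcv))

    def frac_mild(c1):
        return float((cp_ok & (lat["ecog"] <= c1)).mean())

    def frac_most(c0):
        return float((cp_ok & (lat["ecog"] <= c0) & mvi_ok & ~dual).mean())

    cut1 = brentq(lambda c: frac_mild(c) - cfg.target_frac_mild, -3, 4,
                  xtol=1e-6)
    cut0 = brentq(lambda c: frac_most(c) - cfg.target_frac_most, -3, cut1,
                  xtol=1e-6)

    gt = SurrogateGroundTruth(config=cfg, ecog_cut0=cut0, ecog_cut1=cut1,
                              scale_clinical=1.0, scale_score=0.6,
                              kappa=0.0, achieved={})
    table = _covariates_from_latents(cfg, gt, lat)

    tau_w0 = cfg.followup ** cfg.weibull_shape

    def c_index(scale_clin, scale_score, clinical_only):
        """Harrell's C of the (true) linear predictor on censored data.

        The incidence intercept is re-solved at each evaluation so the
        censoring fraction matches the generator's; C is then estimated
        on the frozen pair sample (common random numbers).
        """
        gt.scale_clinical, gt.scale_score = scale_clin, scale_score
        lp_full = _true_linear_predictor(cfg, gt, table)
        kap = brentq(
            lambda k: float(np.mean(1.0 - np.exp(
                -np.exp(np.clip(k + lp_full, -_CLIP, _CLIP)) * tau_w0)))
            - cfg.target_incidence, -30, 10, xtol=1e-6)
        t = (expo / np.exp(np.clip(kap + lp_full, -_CLIP, _CLIP))) \
            ** (1.0 / cfg.weibull_shape)
        obs = np.minimum(t, cens)
        ev = t <= cens
        lp = _true_linear_predictor(cfg, gt, table, clinical_only)
        return _pair_concordance(lp, obs, ev, pair_i, pair_j)

    for _ in range(max_rounds):
        sc = brentq(lambda s: c_index(s, gt.scale_score, True)
                    - cfg.target_c_clinical, 0.05, 8.0, xtol=1e-3)
        ss = brentq(lambda s: c_index(gt.scale_clinical, s, False)
                    - cfg.target_c_full, 0.0, 8.0, xtol=1e-3)
        moved = abs(sc - gt.scale_clinical) + abs(ss - gt.scale_score)
        gt.scale_clinical, gt.scale_score = sc, ss
        if moved < 5e-3:
            break

    lp = _true_linear_predictor(cfg, gt, table)
    tau_w = cfg.followup ** cfg.weibull_shape

    def incidence(kappa):
        return float(np.mean(1.0 - np.exp(-np.exp(
            np.clip(kappa + lp, -_CLIP, _CLIP)) * tau_w)))

    gt.kappa = brentq(lambda k: incidence(k) - cfg.target_incidence,
                      -30, 10, xtol=1e-8)

    masks = eligibility_masks(table)
    achieved = {
        "incidence": incidence(gt.kappa),
        "c_clinical": c_index(gt.scale_clinical, gt.scale_score, True),
        "c_full": c_index(gt.scale_clinical, gt.scale_score, False),
        "frac_mild": float(masks["mildly_restrictive"].mean()),
        "frac_most": float(masks["most_restrictive"].mean()),
    }
    gt.achieved = achieved
    targets = {"incidence": cfg.target_incidence,
               "c_clinical": cfg.target_c_clinical,
               "c_full": cfg.target_c_full,
               "frac_mild": cfg.target_frac_mild,
               "frac_most": cfg.target_frac_most}
    unmet = {k: (achieved[k], targets[k]) for k in targets
             if abs(achieved[k] - targets[k]) > cfg.tol}
    if unmet:
        raise RuntimeError(f"surrogate calibration missed targets: {unmet}")
    return gt


_GT_CACHE: dict[int, SurrogateGroundTruth] = {}


def _default_ground_truth(cfg: SurrogateConfig | None = None):
    key = id(cfg) if cfg is not None else 0
    if key not in _GT_CACHE:
        _GT_CACHE[key] = calibrate_surrogate(cfg)
    return _GT_CACHE[key]


def generate_surrogate_cohort(n: int | None = None,
                              rng: np.random.Generator | None = None,
                              cfg: SurrogateConfig | None = None,
                              ground_truth: SurrogateGroundTruth | None = None,
                              score_coefficient: float | None = None,
                              ) -> pd.DataFrame:
    """Draw a synthetic HCC-like cohort table (complete, no missing data).

    Covariates come from the calibrated single-factor copula; death
    times from the ground-truth Weibull PH model; censoring from a
    uniform follow-up horizon on (1, 12) years, emulating staggered
    study entry. ``score_coefficient`` overrides the calibrated
    risk-score log-hazard (0 makes the score non-prognostic).
    """
    cfg = cfg or SurrogateConfig()
    gt = ground_truth or _default_ground_truth(None if cfg is None else cfg)
    n = n or cfg.n_default
    rng = rng if rng is not None else np.random.default_rng()
    lat = _draw_latents(cfg, n, rng)
    table = _covariates_from_latents(cfg, gt, lat)
    lp_clin = _true_linear_predictor(cfg, gt, table, clinical_only=True)
    ss = gt.scale_score if score_coefficient is None else score_coefficient
    lp = lp_clin + ss * table["risk_score"].to_numpy()
    h = np.exp(np.clip(gt.kappa + lp, -_CLIP, _CLIP))
    t_death = (rng.exponential(1.0, n) / h) ** (1.0 / cfg.weibull_shape)
    t_cens = rng.uniform(1.0, 12.0, n)
    table["observed_time"] = np.minimum(t_death, t_cens)
    table["event"] = (t_death <= t_cens).astype(int)
    return table


# ---------------------------------------------------------------------------
# fitting and simulating from the fitted model
# ---------------------------------------------------------------------------

def fit_cox_with_baseline(table: pd.DataFrame,
                          covariates) -> FittedCoxModel:
    """Cox fit (Efron ties) plus Breslow baseline at the zero profile."""
    covariates = tuple(covariates)
    X = design_matrix(table, covariates)
    if X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        if np.any(np.abs(corr[iu]) > 0.999):
            a, b = np.argwhere(np.abs(corr) > 0.999)[0]
            raise ValueError(
                f"collinear covariates: {covariates[a]} ~ {covariates[b]}")
    time = table["observed_time"].to_numpy(dtype=float)
    event = table["event"].to_numpy().astype(bool)
    if X.shape[1]:
        res = fit_cox(time, event, X, names=covariates)
        coef, ll, ll0 = res.coef, res.loglik, res.loglik_null
    else:
        fit = fit_cox_batch(time[None], event[None], X[None])
        coef, ll, ll0 = np.empty(0), float(fit["loglik"][0]), \
            float(fit["loglik_null"][0])
    times, H0 = breslow_baseline(time, event, X, coef)
    return FittedCoxModel(covariates=covariates, coef=coef,
                          baseline_times=times,
                          baseline_survival=np.exp(-H0),
                          loglik=ll, loglik_null=ll0)


def _stratified_arms(strata: np.ndarray, rng: np.random.Generator):
    """1:1 arms within each stratum (to a one-patient remainder), batched.

    ``strata`` is (R, n); patients are ordered randomly within stratum
    and assigned alternately, which balances arms within every stratum
    regardless of stratum sizes.
    """
    R, n = strata.shape
    key = strata + rng.random((R, n))
    order = np.argsort(key, axis=1)
    alternating = np.tile(np.arange(n) % 2, (R, 1)).astype(float)
    z = np.empty((R, n))
    np.put_along_axis(z, order, alternating, axis=1)
    return z


def _invert_baseline(model: FittedCoxModel, h: np.ndarray,
                     u: np.ndarray, followup: float):
    """Smallest baseline time with S0(t)^h <= U; censored at follow-up."""
    logs0 = np.log(model.baseline_survival)
    # S0(t)^h <= u  <=>  -log S0(t) >= -log(u)/h
    needed = -np.log(u) / h
    idx = np.searchsorted(-logs0, needed, side="left")
    t = np.where(idx < len(logs0),
                 model.baseline_times[np.minimum(idx, len(logs0) - 1)],
                 np.inf)
    event = t <= followup
    return np.minimum(t, followup), event


def simulate_from_fitted_batch(model: FittedCoxModel, table: pd.DataFrame,
                               theta: float, n: int, reps: int,
                               rng: np.random.Generator,
                               stratify_on: str = "tumor_staging",
                               followup: float = 5.0,
                               extra_covariates=()):
    """Batched semi-synthetic trials; returns (Xdesign, z, time, event, rows).

    Covariate rows are resampled from ``table`` with replacement;
    treatment is 1:1 stratified on ``stratify_on``; event times invert
    the fitted step-function survival curve, with administrative
    censoring at ``followup``. ``extra_covariates`` are additional
    columns returned in the design matrix (after the model covariates).
    """
    rows = rng.integers(0, len(table), (reps, n))
    Xt = design_matrix(table, model.covariates)
    lp = Xt @ model.coef if len(model.coef) else np.zeros(len(table))
    h = np.exp(np.clip(lp, -_CLIP, _CLIP))  # control-arm multiplier
    if stratify_on is not None:
        strata = table[stratify_on].to_numpy()[rows]
        z = _stratified_arms(strata.astype(float), rng)
    else:
        z = (rng.random((reps, n)) < 0.5).astype(float)
    hz = h[rows] * theta ** z
    u = rng.random((reps, n))
    time, event = _invert_baseline(model, hz, u, followup)
    cols = [Xt[:, j][rows] for j in range(Xt.shape[1])]
    extra = design_matrix(table, extra_covariates) if extra_covariates else None
    if extra is not None:
        cols += [extra[:, j][rows] for j in range(extra.shape[1])]
    Xd = np.stack([z] + cols, axis=2)
    return Xd, z, time, event, rows


def simulate_from_fitted(model: FittedCoxModel, table: pd.DataFrame,
                         theta: float, n: int, rng: np.random.Generator,
                         stratify_on: str | None = "tumor_staging",
                         followup: float = 5.0) -> Cohort:
    """One semi-synthetic trial cohort (see the batched variant)."""
    if n < 4:
        raise ValueError("n must be at least 4")
    if stratify_on is not None and table[stratify_on].nunique() < 1:
        warnings.warn("empty stratum; falling back to unstratified")
        stratify_on = None
    Xd, z, time, event, _ = simulate_from_fitted_batch(
        model, table, theta, n, 1, rng, stratify_on=stratify_on,
        followup=followup)
    return Cohort(x=Xd[0, :, 1:], z=z[0], t_event=time[0],
                  t_drop=np.full(n, np.inf), time=time[0], event=event[0])


def run_semisynthetic_reduction(table: pd.DataFrame, theta: float = 0.72,
                                n_reference: int = 760, reps: int = 2000,
                                seed: int = 0, n_max: int = 20_000,
                                rel_width: float = 0.02):
    """Sample-size reduction from adding the risk score to the adjustment set.

    Fits the generative Cox model (staging, ECOG, score) on ``table``,
    then locates the sample sizes at which the clinical-only-adjusted
    and clinical-plus-score-adjusted Wald tests reach 80% power, via the
    same probe/bisection/isotonic search as the parametric pipeline.
    Returns a dict with ``N_clinical``, ``N_with_score``, ``reduction``,
    the power gain at ``N_clinical`` and the probe table.
    """
    from .power import _interpolate_target, _even
    from scipy import stats as _st

    model = fit_cox_with_baseline(
        table, CLINICAL_COVARIATES + (SCORE_COVARIATE,))
    alpha, target = 0.05, 0.80

    cache: dict[int, tuple[float, float]] = {}

    def probe(n):
        n = _even(n)
        if n not in cache:
            prng = np.random.default_rng(np.random.SeedSequence([seed, n]))
            pc, ps = [], []
            chunk = max(32, int(2_000_000 / n))
            done = 0
            while done < reps:
                r = min(chunk, reps - done)
                Xd, _, time, event, _ = simulate_from_fitted_batch(
                    model, table, theta, n, r, prng)
                # clinical adjustment: z + staging dummies + ecog1
                from .cox import batch_wald_pvalues
                p1, _ = batch_wald_pvalues(time, event, Xd[:, :, :4])
                p2, _ = batch_wald_pvalues(time, event, Xd)
                pc.append(p1)
                ps.append(p2)
                done += r
            cache[n] = (float((np.concatenate(pc) < alpha).mean()),
                        float((np.concatenate(ps) < alpha).mean()))
        return cache[n]

    def search(which, start):
        lo = hi = _even(start)
        probe(lo)
        for _ in range(40):
            if probe(lo)[which] < target or lo <= 8:
                break
            lo = _even(lo / 1.3)
        for _ in range(40):
            if probe(hi)[which] >= target:
                break
            hi = _even(hi * 1.3)
            if hi > n_max:
                raise RuntimeError("80% power unreachable below n_max")
        while hi - lo > max(2, rel_width * hi):
            mid = _even((lo + hi) / 2)
            if mid in (lo, hi):
                break
            if probe(mid)[which] < target:
                lo = mid
            else:
                hi = mid
        ns = sorted(cache)
        pw = [cache[m][which] for m in ns]
        return _interpolate_target(ns, pw, [reps] * len(ns), target)

    n_score = search(1, int(n_reference * 0.85))
    n_clin = search(0, max(n_reference, _even(n_score * 1.05)))
    p_clin, p_score = probe(_even(n_clin))
    return {
        "N_clinical": _even(n_clin), "N_with_score": _even(n_score),
        "reduction": 1.0 - n_score / n_clin,
        "power_gain_at_N_clinical": p_score - p_clin,
        "theta": theta, "n_reference": n_reference,
        "probes": pd.DataFrame(
            [(m, *cache[m]) for m in sorted(cache)],
            columns=["n", "power_clinical", "power_with_score"]),
    }
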