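"""Trial-design scenario containers.

A :class:`TrialScenario` collects the design parameters of a simulated
two-arm time-to-event trial: the treatment hazard ratio ``theta``, the
Weibull shape ``w`` of the baseline event-time distribution, the
exponential drop-out rate ``d``, the administrative follow-up horizon,
and the two calibration targets — control-arm cumulative incidence
``Lambda_target`` at the end of follow-up and control-arm concordance
``C_target`` of the prognostic covariate.

:class:`CalibratedScenario` adds the solved auxiliary parameters
``kappa`` (log-hazard intercept) and ``beta`` (covariate log-hazard
ratio per SD) plus calibration diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TrialScenario:
    """Design parameters of a simulated 1:1 randomized time-to-event trial.

    Parameters
    ----------
    theta : float
        Treatment hazard ratio (> 0); ``theta < 1`` is a beneficial effect.
    w : float
        Weibull shape of the event-time distribution (> 0).
    d : float
        Drop-out rate of the exponential censoring process (events/year, >= 0).
    Lambda_target : float
        Control-arm cumulative incidence at the end of follow-up, in (0, 1).
        This is the net event probability (Kaplan-Meier estimand), i.e. the
        probability of an event ignoring drop-out.
    C_target : float
        Control-arm concordance index of the covariate, in [0.5, 1).
    followup : float
        Administrative censoring horizon in years (default 5).
    alpha : float
        Two-sided significance level of the Wald test (default 0.05).
    power_target : float
        Target power for sample-size determination (default 0.80).
    """

    theta: float
    w: float = 1.5
    d: float = 0.0
    Lambda_target: float = 0.5
    C_target: float = 0.65
    followup: float = 5.0
    alpha: float = 0.05
    power_target: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 < self.Lambda_target < 1.0):
            raise ValueError(f"Lambda_target must be in (0,1), got {self.Lambda_target}")
        if not (0.5 <= self.C_target < 1.0):
            raise ValueError(f"C_target must be in [0.5,1), got {self.C_target}")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.w <= 0:
            raise ValueError("w must be > 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.followup <= 0:
            raise ValueError("followup must be > 0")


@dataclass(frozen=True)
class CalibratedScenario:
    """A :class:`TrialScenario` together with the solved (kappa, beta).

    ``achieved_Lambda`` and ``achieved_C`` re-evaluate the two target
    functions at the solution; ``residuals`` holds the absolute gaps
    ``(|achieved_Lambda - Lambda_target|, |achieved_C - C_target|)``.
    """

    scenario: TrialScenario
    kappa: float
    beta: float
    achieved_Lambda: float
    achieved_C: float
    residuals: tuple[float, float] = field(default=(0.0, 0.0))
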