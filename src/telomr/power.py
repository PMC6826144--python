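"""Analytic power for summary-statistic MR, normal (non-centrality) approximation.

Binary outcomes: power to detect an odds ratio per SD of the exposure given
the instrument R², the sample size and the case fraction; continuous
outcomes: power for an SD-per-SD effect.  The critical-value convention was
calibrated against the study design this mirrors: one-sided z for binary
rows, two-sided for continuous rows; both are available behind ``convention``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .errors import ValidationError

DEFAULT_ALPHA = 0.01
LOW_POWER_THRESHOLD = 0.80


@dataclass
class PowerSpec:
    """Inputs to one power calculation.

    ``effect`` is an odds ratio per SD of exposure for binary outcomes
    (``case_fraction`` required) or an SD change per SD for continuous ones.
    """

    n: int
    r2: float
    effect: float
    alpha: float = DEFAULT_ALPHA
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if not 0 < self.r2 < 1:
            raise ValidationError(f"r2 {self.r2} outside (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")
        if self.case_fraction is not None and not 0 < self.case_fraction < 1:
            raise ValidationError(f"case fraction {self.case_fraction} outside (0, 1)")


def _z_crit(alpha: float, convention: str) -> float:
    if convention == "one_sided":
        return norm.ppf(1.0 - alpha)
    if convention == "two_sided":
        return norm.ppf(1.0 - alpha / 2.0)
    raise ValidationError(f"unknown convention {convention!r}")


def power_binary(spec: PowerSpec, convention: str = "one_sided") -> float:
    """Power to detect an odds ratio per SD of exposure, binary outcome.

    ``Phi( sqrt(n * r2 * K * (1-K)) * |ln OR| - z_crit )`` with K the case
    fraction.  The effect enters on the log-odds scale.
    """
    if spec.case_fraction is None:
        raise ValidationError("case_fraction required for a binary outcome")
    if spec.effect <= 0:
        raise ValidationError("odds ratio must be positive")
    import math

    k = spec.case_fraction
    ncp = math.sqrt(spec.n * spec.r2 * k * (1.0 - k)) * abs(math.log(spec.effect))
    return float(norm.cdf(ncp - _z_crit(spec.alpha, convention)))


def power_continuous(spec: PowerSpec, convention: str = "two_sided") -> float:
    """Power to detect an SD-per-SD effect on a continuous outcome.

    ``Phi( sqrt(n * r2) * |beta| - z_crit )``.
    """
    import math

    ncp = math.sqrt(spec.n * spec.r2) * abs(spec.effect)
    return float(norm.cdf(ncp - _z_crit(spec.alpha, convention)))


def flag_low_power(power: float, threshold: float = LOW_POWER_THRESHOLD) -> bool:
    """True iff power is strictly below the threshold (default 80%)."""
    if not 0 <= power <= 1:
        raise ValidationError(f"power {power} outside [0, 1]")
    return power < threshold
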