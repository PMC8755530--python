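"""Power approximation for two-sample MR with a binary outcome.

The effective-sample-size argument: an MR analysis behaves like a direct
exposure-outcome study whose sample size is the outcome GWAS sample size
multiplied by the variance in the exposure explained by the instruments
(r2).  On the log-odds scale, with case fraction K, the detectable
effect at two-sided level alpha and power 1 - b satisfies

    |log OR| = (z_{1-alpha/2} + z_{1-b}) / sqrt(N * r2 * K * (1 - K))

and inversely

    power = Phi( sqrt(N * r2 * K * (1 - K)) * |log OR| - z_{1-alpha/2} ).

The K(1-K) factor is the variance of the binary outcome; for a
continuous (standardised) outcome the same formulae apply with that
factor replaced by 1.  z quantiles are used at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .errors import ConfigError

__all__ = ["PowerQuery", "PowerResult", "detectable_or", "power_at_or"]


@dataclass(frozen=True)
class PowerQuery:
    """Inputs to the MR power approximation for a binary outcome."""

    n_cases: int
    n_controls: int
    r2_instruments: float
    alpha: float = 0.05
    target_power: float = 0.80
    odds_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("n_cases and n_controls must be positive")
        if not (0.0 < self.r2_instruments < 1.0):
            raise ConfigError(f"r2_instruments must lie in (0, 1), got {self.r2_instruments}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.target_power < 1.0):
            raise ConfigError(f"target_power must lie in (0, 1), got {self.target_power}")
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise ConfigError(f"odds_ratio must be positive, got {self.odds_ratio}")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


@dataclass(frozen=True)
class PowerResult:
    """Detectable odds ratios (both directions) at the target power."""

    or_protective: float
    or_harmful: float
    n_total: int
    case_fraction: float
    r2_instruments: float
    alpha: float
    target_power: float


def _ncp_scale(q: PowerQuery) -> float:
    k = q.case_fraction
    if not (0.0 < k < 1.0):
        raise ConfigError(f"degenerate case fraction {k}")
    return math.sqrt(q.n_total * q.r2_instruments * k * (1.0 - k))


def detectable_or(q: PowerQuery) -> PowerResult:
    """Smallest detectable odds ratio per SD of exposure, both directions."""
    z_alpha = float(stats.norm.ppf(1.0 - q.alpha / 2.0))
    z_power = float(stats.norm.ppf(q.target_power))
    log_or = (z_alpha + z_power) / _ncp_scale(q)
    return PowerResult(
        or_protective=math.exp(-log_or),
        or_harmful=math.exp(log_or),
        n_total=q.n_total,
        case_fraction=q.case_fraction,
        r2_instruments=q.r2_instruments,
        alpha=q.alpha,
        target_power=q.target_power,
    )


def power_at_or(q: PowerQuery) -> float:
    """Power to detect a given odds ratio at the query's alpha.

    At OR = 1 this returns the one-sided tail Phi(-z_{1-alpha/2})
    (about alpha/2), the probability of rejecting in one direction
    under the null.
    """
    if q.odds_ratio is None:
        raise ConfigError("odds_ratio must be set for a power query")
    z_alpha = float(stats.norm.ppf(1.0 - q.alpha / 2.0))
    return float(stats.norm.cdf(_ncp_scale(q) * abs(math.log(q.odds_ratio)) - z_alpha))
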