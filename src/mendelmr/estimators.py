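"""Causal-effect estimators for two-sample MR on harmonised variants.

Implemented estimators
----------------------
* Wald ratio: per-variant estimate theta_j = Gamma_j / gamma_j with the
  first-order delta-method SE, se(Gamma_j)/|gamma_j|.
* IVW: inverse-variance-weighted meta-analysis of the Wald ratios,
  algebraically a weighted regression of outcome on exposure effects
  through the origin.  In ``auto`` mode the SE is inflated by the
  multiplicative dispersion sqrt(max(1, Q/(J-1))) when more than three
  instruments are used (fixed effects otherwise), Q being Cochran's
  heterogeneity statistic.
* Weighted median: the 50% point of the inverse-variance-weighted
  empirical distribution of Wald ratios, linearly interpolated;
  consistent when valid instruments carry more than half the weight.
  SE by seeded parametric bootstrap.
* MR-Egger: weighted regression of outcome on exposure effects with a
  free intercept estimating average directional pleiotropy; exposure
  effects are oriented non-negative first so the intercept has a single
  interpretable sign convention.
* MR-RAPS (simple model): maximiser of the profile log-likelihood that
  accounts for sampling error in both the exposure and outcome effects;
  no overdispersion parameter and squared-error loss.

All p-values and confidence intervals use the normal reference
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    CollinearityError,
    ConvergenceError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .harmonise import HarmonisedVariant
from .records import Method, ReportRow, TraitType

__all__ = [
    "MrResult",
    "kept_only",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "mr_egger",
    "mr_raps",
    "to_odds_scale",
]

Z_975 = float(stats.norm.ppf(0.975))


@dataclass
class MrResult:
    """One estimator's output on the beta (log-odds for binary) scale."""

    method: Method
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    cochran_q: Optional[float] = None
    dispersion_phi: Optional[float] = None
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None


def _two_sided_p(beta: float, se: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(beta) / se)))


def _result(method: Method, n: int, beta: float, se: float, **extra) -> MrResult:
    return MrResult(
        method=method,
        n_snp=n,
        beta=beta,
        se=se,
        ci_low=beta - Z_975 * se,
        ci_high=beta + Z_975 * se,
        pval=_two_sided_p(beta, se),
        **extra,
    )


def kept_only(hs: Sequence[HarmonisedVariant]) -> list[HarmonisedVariant]:
    """Filter to records harmonisation kept; drops must never be estimated."""
    return [h for h in hs if h.kept]


def _arrays(hs: Sequence[HarmonisedVariant]) -> tuple[np.ndarray, ...]:
    hs = kept_only(hs)
    be = np.array([h.beta_exposure for h in hs], dtype=float)
    se_e = np.array([h.se_exposure for h in hs], dtype=float)
    bo = np.array([h.beta_outcome for h in hs], dtype=float)
    se_o = np.array([h.se_outcome for h in hs], dtype=float)
    return be, se_e, bo, se_o


def wald_ratio(h: HarmonisedVariant) -> tuple[float, float]:
    """Single-variant causal estimate and first-order delta-method SE."""
    if not h.kept:
        raise UndefinedRatioError(f"{h.variant_id}: record was dropped at harmonisation")
    if h.beta_exposure == 0:
        raise UndefinedRatioError(f"{h.variant_id}: zero exposure effect, Wald ratio undefined")
    return h.beta_outcome / h.beta_exposure, h.se_outcome / abs(h.beta_exposure)


def ivw(
    hs: Sequence[HarmonisedVariant],
    effects_mode: str = "auto",
) -> MrResult:
    """Inverse-variance-weighted meta-analysis of per-variant Wald ratios.

    Weights are w_j = beta_exposure_j^2 / se_outcome_j^2 (the inverse
    first-order variance of each ratio).  ``effects_mode``:

    * ``"fixed"`` — SE = 1/sqrt(sum w_j);
    * ``"multiplicative_random"`` — fixed-effects SE scaled by
      sqrt(max(1, Q/(J-1))), never deflated below fixed effects;
    * ``"auto"`` — multiplicative random effects when J > 3, fixed
      effects otherwise (the convention for small instrument counts).
    """
    be, _, bo, se_o = _arrays(hs)
    n = len(be)
    if n < 1:
        raise InsufficientInstrumentsError("IVW requires at least one kept variant")
    if np.any(be == 0):
        raise UndefinedRatioError("IVW undefined with a zero exposure effect")
    if effects_mode not in ("auto", "fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_mode {effects_mode!r}")

    theta = bo / be
    w = be**2 / se_o**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - beta) ** 2))

    use_random = effects_mode == "multiplicative_random" or (
        effects_mode == "auto" and n > 3
    )
    if use_random and n >= 2:
        phi = max(1.0, q / (n - 1))
    else:
        phi = 1.0
    se = se_fixed * math.sqrt(phi)
    return _result(Method.IVW, n, beta, se, cochran_q=q, dispersion_phi=phi)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50% point of the weighted ratio distribution."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ww = w[order] / np.sum(w)
    cum = np.cumsum(ww)
    p = cum - ww / 2.0
    if p[0] >= 0.5:
        return float(th[0])
    if p[-1] <= 0.5:
        return float(th[-1])
    return float(np.interp(0.5, p, th))


def weighted_median(
    hs: Sequence[HarmonisedVariant],
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> MrResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    The point estimate interpolates the inverse-variance-weighted
    empirical quantile function of the Wald ratios at probability 0.5.
    The SE is the standard deviation of the estimate over
    ``bootstrap_reps`` parametric resamples in which both effect
    estimates are redrawn from normal distributions centred at their
    observed values with their reported SEs (weights recomputed per
    resample).  ``seed`` makes the bootstrap reproducible.
    """
    be, se_e, bo, se_o = _arrays(hs)
    n = len(be)
    if n < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 kept variants, got {n}"
        )
    theta = bo / be
    w = be**2 / se_o**2
    beta = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    be_star = be + rng.standard_normal((bootstrap_reps, n)) * se_e
    bo_star = bo + rng.standard_normal((bootstrap_reps, n)) * se_o
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_star = bo_star / be_star
        w_star = be_star**2 / se_o**2
    draws = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        draws[r] = _weighted_median_point(theta_star[r], w_star[r])
    se = float(np.std(draws, ddof=1))
    return _result(Method.weighted_median, n, beta, se)


def mr_egger(hs: Sequence[HarmonisedVariant]) -> MrResult:
    """MR-Egger regression: weighted fit with a pleiotropy intercept.

    Variants are first oriented so every exposure effect is
    non-negative (both betas negated where needed), then outcome effects
    are regressed on exposure effects with an intercept, weights
    1/se_outcome^2.  Both SEs are scaled by the multiplicative residual
    dispersion sqrt(max(1, RSS_w/(J-2))).  The slope estimates the
    causal effect under InSIDE; the intercept estimates average
    directional pleiotropy.
    """
    be, _, bo, se_o = _arrays(hs)
    n = len(be)
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 kept variants, got {n}")

    flip = np.sign(be)
    flip[flip == 0] = 1.0
    x = be * flip
    y = bo * flip
    if np.allclose(x, x[0]):
        raise CollinearityError("all exposure effects identical after orientation")

    w = 1.0 / se_o**2
    # Weighted normal equations for [intercept, slope].
    sw = np.sum(w)
    swx = np.sum(w * x)
    swxx = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    xtx = np.array([[sw, swx], [swx, swxx]])
    xty = np.array([swy, swxy])
    coef = np.linalg.solve(xtx, xty)
    intercept, slope = float(coef[0]), float(coef[1])

    resid = y - intercept - slope * x
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (n - 2))
    cov = np.linalg.inv(xtx) * phi
    se_intercept = float(math.sqrt(cov[0, 0]))
    se_slope = float(math.sqrt(cov[1, 1]))

    return _result(
        Method.MR_Egger,
        n,
        slope,
        se_slope,
        cochran_q=rss_w,
        dispersion_phi=phi,
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_p=_two_sided_p(intercept, se_intercept),
    )


def _raps_score(beta: float, be, se_e, bo, se_o) -> float:
    """Derivative of the profile log-likelihood in beta."""
    r = bo - beta * be
    v = se_o**2 + beta**2 * se_e**2
    return float(np.sum(r * be / v + beta * se_e**2 * r**2 / v**2))


def _raps_loglik(beta: float, be, se_e, bo, se_o) -> float:
    r = bo - beta * be
    v = se_o**2 + beta**2 * se_e**2
    return float(-0.5 * np.sum(r**2 / v))


def mr_raps(hs: Sequence[HarmonisedVariant]) -> MrResult:
    """Robust-adjusted-profile-score estimator, simple model.

    Maximises the profile log-likelihood

        l(beta) = -1/2 sum_j (Gamma_j - beta * gamma_j)^2
                             / (se_Gamma_j^2 + beta^2 * se_gamma_j^2)

    which, unlike IVW, propagates the exposure-side sampling error.  The
    score equation is solved by bracketed root finding around the
    fixed-effects IVW estimate (brackets widened geometrically); the SE
    comes from the numerical observed information at the optimum.  No
    overdispersion parameter and no robust loss are fitted.
    """
    be, se_e, bo, se_o = _arrays(hs)
    n = len(be)
    if n < 2:
        raise InsufficientInstrumentsError(f"MR-RAPS requires >= 2 kept variants, got {n}")

    anchor = ivw(kept_only(list(hs)), effects_mode="fixed")
    half_width = 10.0 * anchor.se
    bracket = None
    for _ in range(8):
        lo, hi = anchor.beta - half_width, anchor.beta + half_width
        if _raps_score(lo, be, se_e, bo, se_o) * _raps_score(hi, be, se_e, bo, se_o) < 0:
            bracket = (lo, hi)
            break
        half_width *= 4.0
    if bracket is None:
        raise ConvergenceError(
            f"no sign change of the profile score in [{anchor.beta - half_width:g}, "
            f"{anchor.beta + half_width:g}]"
        )
    beta = float(
        optimize.brentq(_raps_score, *bracket, args=(be, se_e, bo, se_o), xtol=1e-12)
    )

    # Numerical observed information: central difference of the score.
    h = 1e-6 * max(1.0, abs(beta))
    info = -(
        _raps_score(beta + h, be, se_e, bo, se_o) - _raps_score(beta - h, be, se_e, bo, se_o)
    ) / (2.0 * h)
    if info <= 0:
        raise ConvergenceError("profile score root is not an interior maximum")
    se = float(1.0 / math.sqrt(info))
    return _result(Method.MR_RAPS, n, beta, se)


def to_odds_scale(
    result: MrResult,
    outcome_id: str = "",
    trait_type: TraitType | str = TraitType.binary,
    selection_tier: str = "genome_wide",
) -> ReportRow:
    """Convert an estimate to the reporting scale.

    For binary outcomes (log-odds betas) the effect and CI bounds are
    exponentiated to odds ratios per SD of exposure; continuous outcomes
    pass through untransformed with the odds-ratio field absent.
    """
    trait_type = TraitType(trait_type)
    if trait_type is TraitType.binary:
        or_, lo, hi = math.exp(result.beta), math.exp(result.ci_low), math.exp(result.ci_high)
    else:
        or_, lo, hi = None, result.ci_low, result.ci_high
    return ReportRow(
        outcome_id=outcome_id,
        method=result.method,
        n_snp=result.n_snp,
        beta=result.beta,
        se=result.se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        pval=result.pval,
        egger_intercept=result.intercept,
        intercept_se=result.intercept_se,
        intercept_p=result.intercept_p,
        selection_tier=selection_tier,
    )
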