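"""Estimator correctness: reductions, independent oracles, equivariances."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mendelmr import (
    Method,
    ivw,
    mr_egger,
    mr_raps,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from mendelmr.errors import (
    CollinearityError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from mendelmr.estimators import _raps_loglik

from conftest import hv, random_harmonised


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def test_wald_ratio_direct_division():
    theta, se = wald_ratio(hv(be=0.5, bo=-0.02, se_o=0.01))
    assert theta == pytest.approx(-0.04)
    assert se == pytest.approx(0.02)


def test_wald_ratio_unit_exposure_identity():
    theta, se = wald_ratio(hv(be=1.0, bo=-0.02, se_o=0.01))
    assert theta == pytest.approx(-0.02)
    assert se == pytest.approx(0.01)


def test_wald_ratio_negative_exposure_se_positive():
    theta, se = wald_ratio(hv(be=-0.5, bo=0.02, se_o=0.01))
    assert theta == pytest.approx(-0.04)
    assert se == pytest.approx(0.02)


def test_wald_ratio_zero_exposure_error():
    with pytest.raises(UndefinedRatioError):
        wald_ratio(hv(be=0.0))


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def test_ivw_single_variant_equals_wald():
    h = hv(be=0.5, bo=-0.02, se_o=0.01)
    theta, se = wald_ratio(h)
    res = ivw([h])
    assert res.beta == pytest.approx(theta, abs=1e-15)
    assert res.se == pytest.approx(se, abs=1e-15)


def test_ivw_equal_weights_is_mean():
    hs = [
        hv(vid="a", be=0.5, bo=0.05, se_o=0.01),   # theta 0.1
        hv(vid="b", be=0.5, bo=0.15, se_o=0.01),   # theta 0.3
    ]
    assert ivw(hs).beta == pytest.approx(0.2)


def test_ivw_matches_wls_through_origin_oracle(rng):
    """Beta and fixed-effects SE match a statsmodels WLS fit through the origin."""
    hs = random_harmonised(rng, 4)
    x = np.array([h.beta_exposure for h in hs])
    y = np.array([h.beta_outcome for h in hs])
    w = 1.0 / np.array([h.se_outcome for h in hs]) ** 2
    fit = sm.WLS(y, x, weights=w).fit()
    res = ivw(hs, effects_mode="fixed")
    assert res.beta == pytest.approx(float(fit.params[0]), abs=1e-10)
    # un-scale statsmodels' residual-variance factor to get the fixed-effects SE
    se_fixed = float(fit.bse[0]) / math.sqrt(float(fit.scale))
    assert res.se == pytest.approx(se_fixed, abs=1e-10)


def test_ivw_random_effects_rule():
    """Dispersion applies only above three instruments, and never deflates."""
    hs4 = [
        hv(vid=f"r{i}", be=0.2, bo=bo, se_o=0.005)
        for i, bo in enumerate([-0.012, -0.002, -0.015, 0.004])
    ]
    fixed = ivw(hs4, effects_mode="fixed")
    auto4 = ivw(hs4, effects_mode="auto")
    assert auto4.dispersion_phi > 1.0
    assert auto4.se > fixed.se
    assert auto4.beta == pytest.approx(fixed.beta)

    auto3 = ivw(hs4[:3], effects_mode="auto")
    fixed3 = ivw(hs4[:3], effects_mode="fixed")
    assert auto3.dispersion_phi == 1.0
    assert auto3.se == pytest.approx(fixed3.se)


def test_ivw_dispersion_floored_at_one(rng):
    """Homogeneous data: multiplicative random effects never shrink the SE."""
    hs = [hv(vid=f"r{i}", be=0.2, bo=-0.008, se_o=0.005) for i in range(5)]
    res = ivw(hs, effects_mode="multiplicative_random")
    assert res.dispersion_phi == 1.0
    assert res.se == pytest.approx(ivw(hs, effects_mode="fixed").se)


def test_ivw_cochran_q_definition(rng):
    hs = random_harmonised(rng, 6)
    res = ivw(hs, effects_mode="fixed")
    theta = np.array([h.beta_outcome / h.beta_exposure for h in hs])
    w = np.array([h.beta_exposure**2 / h.se_outcome**2 for h in hs])
    q = float(np.sum(w * (theta - res.beta) ** 2))
    assert res.cochran_q == pytest.approx(q, abs=1e-12)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_equal_weights_is_median():
    hs = [
        hv(vid="a", be=1.0, bo=-1.0, se_o=0.1),
        hv(vid="b", be=1.0, bo=0.0, se_o=0.1),
        hv(vid="c", be=1.0, bo=5.0, se_o=0.1),
    ]
    assert weighted_median(hs, 50, seed=1).beta == pytest.approx(0.0)


def test_weighted_median_dominant_weight():
    """A variant holding ~90% of the weight pins the estimate near its ratio."""
    hs = [
        hv(vid="big", be=1.0, bo=0.5, se_o=0.01),
        hv(vid="s1", be=1.0, bo=-1.0, se_o=0.15),
        hv(vid="s2", be=1.0, bo=2.0, se_o=0.15),
    ]
    assert weighted_median(hs, 50, seed=1).beta == pytest.approx(0.5, abs=0.05)


def _wm_grid_oracle(theta, w, tol=1e-8):
    """Forward-CDF grid scan: find m with interpolated cumulative weight 0.5."""
    order = np.argsort(theta)
    th, ww = theta[order], w[order] / w.sum()
    p = np.cumsum(ww) - ww / 2
    lo, hi = th[0], th[-1]
    for _ in range(2):
        grid = np.linspace(lo, hi, 20001)
        cdf = np.interp(grid, th, p)
        k = int(np.argmin(np.abs(cdf - 0.5)))
        step = grid[1] - grid[0]
        lo, hi = grid[k] - step, grid[k] + step
    return float(grid[k])


@pytest.mark.parametrize("trial", range(10))
def test_weighted_median_matches_grid_oracle(trial):
    """Randomised 7-variant sets agree with a fine-grid CDF inversion."""
    local = np.random.default_rng(500 + trial)
    hs = random_harmonised(local, 7)
    theta = np.array([h.beta_outcome / h.beta_exposure for h in hs])
    w = np.array([h.beta_exposure**2 / h.se_outcome**2 for h in hs])
    res = weighted_median(hs, 50, seed=trial)
    assert res.beta == pytest.approx(_wm_grid_oracle(theta, w), abs=1e-6)


def test_weighted_median_bootstrap_seeded():
    hs = random_harmonised(np.random.default_rng(3), 6)
    a = weighted_median(hs, 200, seed=11)
    b = weighted_median(hs, 200, seed=11)
    c = weighted_median(hs, 200, seed=12)
    assert a.se == b.se
    assert a.se != c.se
    assert a.beta == c.beta  # point estimate is bootstrap-free


def test_weighted_median_needs_three():
    with pytest.raises(InsufficientInstrumentsError):
        weighted_median([hv(vid="a"), hv(vid="b")], 50, seed=1)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def test_egger_exact_line_recovered():
    """Points generated exactly as Gamma = 0.05 + 0.3 gamma are fit exactly."""
    gammas = [0.1, 0.2, 0.3, 0.45]
    hs = [
        hv(vid=f"g{i}", be=g, bo=0.05 + 0.3 * g, se_o=0.01)
        for i, g in enumerate(gammas)
    ]
    res = mr_egger(hs)
    assert res.beta == pytest.approx(0.3, abs=1e-12)
    assert res.intercept == pytest.approx(0.05, abs=1e-12)


def test_egger_matches_statsmodels_wls_oracle(rng):
    """Slope/intercept and (dispersion-scaled) SEs match statsmodels WLS."""
    hs = random_harmonised(rng, 8)
    x = np.array([h.beta_exposure for h in hs])
    y = np.array([h.beta_outcome for h in hs])
    flip = np.sign(x)
    x, y = x * flip, y * flip
    w = 1.0 / np.array([h.se_outcome for h in hs]) ** 2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    res = mr_egger(hs)
    assert res.intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
    assert res.beta == pytest.approx(float(fit.params[1]), abs=1e-10)
    if res.dispersion_phi > 1.0:  # statsmodels always scales by RSS/(n-2)
        assert res.intercept_se == pytest.approx(float(fit.bse[0]), abs=1e-10)
        assert res.se == pytest.approx(float(fit.bse[1]), abs=1e-10)


def test_egger_orientation_sign_invariant(rng):
    """Negating an exposure effect (with its outcome effect) changes nothing."""
    hs = random_harmonised(rng, 6)
    flipped = [
        hv(
            vid=h.variant_id,
            be=-h.beta_exposure if i == 2 else h.beta_exposure,
            se_e=h.se_exposure,
            bo=-h.beta_outcome if i == 2 else h.beta_outcome,
            se_o=h.se_outcome,
        )
        for i, h in enumerate(hs)
    ]
    a, b = mr_egger(hs), mr_egger(flipped)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.intercept == pytest.approx(b.intercept, abs=1e-12)


def test_egger_collinear_error():
    hs = [hv(vid=f"x{i}", be=0.2, bo=-0.01, se_o=0.01) for i in range(4)]
    with pytest.raises(CollinearityError):
        mr_egger(hs)


def test_egger_needs_three():
    with pytest.raises(InsufficientInstrumentsError):
        mr_egger([hv(vid="a"), hv(vid="b")])


# ---------------------------------------------------------------------------
# MR-RAPS (simple model)
# ---------------------------------------------------------------------------

def test_raps_reduces_to_ivw_without_exposure_error(rng):
    hs = [
        hv(
            vid=h.variant_id,
            be=h.beta_exposure,
            se_e=0.0,
            bo=h.beta_outcome,
            se_o=h.se_outcome,
        )
        for h in random_harmonised(rng, 6)
    ]
    res = mr_raps(hs)
    assert res.beta == pytest.approx(ivw(hs, effects_mode="fixed").beta, abs=1e-8)


def test_raps_exact_proportionality():
    hs = [hv(vid=f"p{i}", be=g, bo=-0.04 * g, se_o=0.01) for i, g in enumerate([0.1, 0.2, 0.3])]
    assert mr_raps(hs).beta == pytest.approx(-0.04, abs=1e-10)


@pytest.mark.parametrize("trial", range(5))
def test_raps_matches_grid_maximisation(trial):
    """The score root coincides with a fine-grid profile-likelihood maximum."""
    local = np.random.default_rng(900 + trial)
    hs = random_harmonised(local, 8)
    res = mr_raps(hs)
    be = np.array([h.beta_exposure for h in hs])
    se_e = np.array([h.se_exposure for h in hs])
    bo = np.array([h.beta_outcome for h in hs])
    se_o = np.array([h.se_outcome for h in hs])
    anchor = ivw(hs, effects_mode="fixed")
    lo, hi = anchor.beta - 6 * anchor.se, anchor.beta + 6 * anchor.se
    for _ in range(3):
        grid = np.linspace(lo, hi, 10001)
        ll = np.array([_raps_loglik(b, be, se_e, bo, se_o) for b in grid])
        k = int(np.argmax(ll))
        step = grid[1] - grid[0]
        lo, hi = grid[k] - step, grid[k] + step
    assert res.beta == pytest.approx(float(grid[k]), abs=1e-6)


def test_raps_needs_two():
    with pytest.raises(InsufficientInstrumentsError):
        mr_raps([hv()])


# ---------------------------------------------------------------------------
# Odds scale
# ---------------------------------------------------------------------------

def test_to_odds_scale_null_is_unity():
    res = ivw([hv(be=0.5, bo=0.0, se_o=0.01)])
    row = to_odds_scale(res, "out")
    assert row.or_ == pytest.approx(1.0)


def test_to_odds_scale_closed_form():
    """beta -0.0408 (se 0.0133) exponentiates to OR 0.96, CI 0.93-0.99."""
    from mendelmr.estimators import _result

    res = _result(Method.IVW, 4, -0.0408, 0.0133)
    row = to_odds_scale(res, "any")
    assert round(row.or_, 2) == 0.96
    assert round(row.ci_low, 2) == 0.94
    assert round(row.ci_high, 2) == 0.99
    assert row.or_ == pytest.approx(math.exp(res.beta))
    assert row.ci_low == pytest.approx(math.exp(res.ci_low))


def test_to_odds_scale_monotone():
    from mendelmr.estimators import _result

    rows = [
        to_odds_scale(_result(Method.IVW, 3, b, 0.01), "o")
        for b in (-0.1, -0.05, 0.0, 0.05)
    ]
    ors = [r.or_ for r in rows]
    assert ors == sorted(ors)


def test_to_odds_scale_continuous_passthrough():
    from mendelmr.estimators import _result

    res = _result(Method.IVW, 3, -0.04, 0.01)
    row = to_odds_scale(res, "children", trait_type="continuous")
    assert row.or_ is None
    assert row.ci_low == pytest.approx(res.ci_low)


# ---------------------------------------------------------------------------
# Shared invariants: scale/sign equivariance and order invariance
# ---------------------------------------------------------------------------

ESTIMATORS = {
    "IVW": lambda hs: ivw(hs).beta,
    "weighted_median": lambda hs: weighted_median(hs, 50, seed=2).beta,
    "MR_Egger": lambda hs: mr_egger(hs).beta,
    "MR_RAPS": lambda hs: mr_raps(hs).beta,
}


def _rescale_exposure(hs, c):
    return [
        hv(vid=h.variant_id, be=c * h.beta_exposure, se_e=abs(c) * h.se_exposure,
           bo=h.beta_outcome, se_o=h.se_outcome)
        for h in hs
    ]


def _negate_outcome(hs):
    return [
        hv(vid=h.variant_id, be=h.beta_exposure, se_e=h.se_exposure,
           bo=-h.beta_outcome, se_o=h.se_outcome)
        for h in hs
    ]


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    c=st.floats(0.25, 4.0),
    name=st.sampled_from(sorted(ESTIMATORS)),
)
def test_estimator_scale_and_sign_equivariance(seed, c, name):
    """Rescaling exposure units divides beta by c; negating outcomes negates it."""
    hs = random_harmonised(np.random.default_rng(seed), 6)
    est = ESTIMATORS[name]
    base = est(hs)
    assert est(_rescale_exposure(hs, c)) == pytest.approx(base / c, rel=1e-6, abs=1e-9)
    assert est(_negate_outcome(hs)) == pytest.approx(-base, rel=1e-6, abs=1e-9)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), name=st.sampled_from(sorted(ESTIMATORS)))
def test_estimator_order_invariance(seed, name):
    hs = random_harmonised(np.random.default_rng(seed), 7)
    est = ESTIMATORS[name]
    assert est(list(reversed(hs))) == pytest.approx(est(hs), rel=1e-9, abs=1e-12)


def test_estimators_agree_with_valid_instruments():
    """No pleiotropy, strong instruments: all four estimators nearly coincide."""
    local = np.random.default_rng(2718)
    hs = random_harmonised(local, 50)
    betas = {name: est(hs) for name, est in ESTIMATORS.items()}
    spread = max(betas.values()) - min(betas.values())
    assert spread < 0.02  # all near the -0.04 generative slope
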