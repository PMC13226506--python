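import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from targetmr import (
    IVWEstimator,
    beta_to_or,
    ivw,
    mode_estimate,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from targetmr.estimators import InsufficientInstrumentsError, _weighted_median

from conftest import make_pairs, random_pairs


# --- Wald ratio -------------------------------------------------------------

def test_wald_ratio_arithmetic():
    est = wald_ratio(make_pairs([0.5], [0.05], [-0.1], [0.02]))
    assert est.beta == pytest.approx(-0.2)
    assert est.se == pytest.approx(0.02 / 0.5)
    assert wald_ratio(make_pairs([0.5], [0.05], [0.0], [0.02])).beta == 0.0


def test_wald_ratio_rejects_zero_exposure_effect():
    with pytest.raises(ZeroDivisionError):
        wald_ratio(make_pairs([0.0], [0.05], [0.1], [0.02]))


def test_wald_ratio_matches_delta_method_oracle(rng):
    for _ in range(50):
        bx, by = rng.normal(0.2, 0.1), rng.normal(0, 0.1)
        sy = rng.uniform(0.01, 0.1)
        if abs(bx) < 1e-3:
            continue
        est = wald_ratio(make_pairs([bx], [0.01], [by], [sy]))
        assert est.beta == pytest.approx(by / bx)
        assert est.se == pytest.approx(sy / abs(bx))  # first-order delta method


# --- IVW --------------------------------------------------------------------

def test_ivw_constant_ratio_is_exact():
    bx = np.array([0.1, 0.2, 0.3])
    pairs = make_pairs(bx, bx * 0 + 0.01, -0.5 * bx, [0.02, 0.03, 0.04])
    est = IVWEstimator().fit(pairs)
    assert est.beta_ == pytest.approx(-0.5)
    assert est.q_ == pytest.approx(0.0, abs=1e-20)


def test_ivw_requires_two_pairs():
    with pytest.raises(InsufficientInstrumentsError):
        ivw(make_pairs([0.1], [0.01], [0.1], [0.02]))


def test_ivw_matches_wls_oracle(rng):
    """Equals weighted least squares through the origin to 1e-10."""
    for _ in range(100):
        pairs = random_pairs(rng, n=int(rng.integers(3, 20)))
        w = 1.0 / pairs["se_out"] ** 2
        fit = sm.WLS(pairs["beta_out"], pairs[["beta_exp"]], weights=w).fit()
        est = IVWEstimator().fit(pairs)
        assert est.beta_ == pytest.approx(fit.params.iloc[0], abs=1e-10)
        # multiplicative random effects: never below the fixed-effect SE
        se_fixed = fit.bse.iloc[0] / np.sqrt(fit.scale)
        assert est.se_ == pytest.approx(max(fit.bse.iloc[0], se_fixed), abs=1e-10)


def test_ivw_equals_precision_weighted_mean_of_ratios(rng):
    """Algebraic identity with ratio-level weights beta_x^2 / se_y^2."""
    pairs = random_pairs(rng, n=10)
    bx, by = pairs["beta_exp"].to_numpy(), pairs["beta_out"].to_numpy()
    sy = pairs["se_out"].to_numpy()
    ratios, w = by / bx, bx**2 / sy**2
    assert ivw(pairs).beta == pytest.approx(np.sum(w * ratios) / np.sum(w), abs=1e-12)


# --- MR-Egger ---------------------------------------------------------------

def test_egger_matches_wls_oracle(rng):
    for _ in range(100):
        pairs = random_pairs(rng, n=int(rng.integers(4, 20)), pleiotropy=0.03)
        sign = np.sign(pairs["beta_exp"]).replace(0, 1)
        bx = (pairs["beta_exp"] * sign).to_numpy()
        by = (pairs["beta_out"] * sign).to_numpy()
        w = 1.0 / pairs["se_out"].to_numpy() ** 2
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        est = mr_egger(pairs)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        se_fixed = fit.bse / np.sqrt(fit.scale)
        assert est.se == pytest.approx(max(fit.bse[1], se_fixed[1]), abs=1e-10)
        assert est.intercept_se == pytest.approx(max(fit.bse[0], se_fixed[0]), abs=1e-10)


def test_egger_requires_three_pairs(rng):
    with pytest.raises(InsufficientInstrumentsError):
        mr_egger(random_pairs(rng, n=2))


def test_egger_orientation_invariance(rng):
    """Flipping the sign of whole pairs leaves the Egger fit unchanged."""
    pairs = random_pairs(rng, n=8, pleiotropy=0.02)
    flipped = pairs.copy()
    flipped.loc[::2, ["beta_exp", "beta_out"]] *= -1
    a, b = mr_egger(pairs), mr_egger(flipped)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.intercept == pytest.approx(b.intercept, abs=1e-12)


# --- weighted median --------------------------------------------------------

def test_weighted_median_equal_weights_is_ordinary_median():
    vals = np.array([-0.4, -0.1, 0.3, 0.8, 1.2])
    assert _weighted_median(vals, np.ones(5)) == pytest.approx(np.median(vals))


def test_weighted_median_estimator_robust_to_minority_invalid(rng):
    """60% valid instruments at theta, 40% corrupted: median near theta,
    IVW pulled away."""
    theta = -0.3
    n_valid, n_bad = 9, 6
    bx = rng.normal(0.2, 0.02, n_valid + n_bad)
    sy = np.full(n_valid + n_bad, 0.01)
    by = theta * bx
    by[n_valid:] += 0.25  # strong directional corruption
    pairs = make_pairs(bx, np.full(n_valid + n_bad, 0.001), by, sy)
    wm = weighted_median(pairs, n_boot=200, seed=1)
    assert wm.beta == pytest.approx(theta, abs=0.05)
    assert abs(ivw(pairs).beta - theta) > 3 * abs(wm.beta - theta)


def test_weighted_median_bootstrap_reproducible(rng):
    pairs = random_pairs(rng, n=10)
    a = weighted_median(pairs, n_boot=300, seed=7)
    b = weighted_median(pairs, n_boot=300, seed=7)
    assert a.se == b.se
    c = weighted_median(pairs, n_boot=300, seed=8)
    assert c.se != a.se


# --- mode estimators --------------------------------------------------------

def test_mode_constant_ratios_returns_that_ratio(rng):
    bx = np.array([0.1, 0.2, 0.4])
    pairs = make_pairs(bx, bx * 0 + 0.01, 0.7 * bx, [0.01, 0.02, 0.03])
    for phi in (0.25, 1.0, 4.0):
        for weighted in (False, True):
            est = mode_estimate(pairs, weighted=weighted, phi=phi,
                                n_boot=50, seed=0)
            assert est.beta == pytest.approx(0.7, abs=1e-9)


def test_mode_finds_heavier_cluster():
    """Bimodal ratios: the estimate lands in the larger cluster."""
    bx = np.full(10, 0.2)
    ratios = np.array([0.5] * 6 + [-0.8] * 4)
    pairs = make_pairs(bx, np.full(10, 0.001), ratios * bx, np.full(10, 0.01))
    est = mode_estimate(pairs, weighted=False, phi=1.0, n_boot=50, seed=0)
    assert est.beta == pytest.approx(0.5, abs=0.1)


def test_mode_rejects_bad_phi(rng):
    with pytest.raises(ValueError):
        mode_estimate(random_pairs(rng, n=5), phi=0.0)


def test_mode_seeded_reproducibility(rng):
    pairs = random_pairs(rng, n=10)
    assert (
        mode_estimate(pairs, n_boot=200, seed=3).se
        == mode_estimate(pairs, n_boot=200, seed=3).se
    )


# --- OR transform and shared invariants -------------------------------------

def test_beta_to_or_reproduces_reported_effects():
    or_, lo, hi = beta_to_or(-0.306, 0.134)
    assert or_ == pytest.approx(0.736, abs=5e-4)
    assert lo == pytest.approx(0.566, abs=5e-3)
    assert hi == pytest.approx(0.958, abs=5e-3)
    assert beta_to_or(0.0, 0.1)[0] == 1.0
    # ln(1.588) is the step-1 effect 0.463 quoted on the OR scale; both
    # figures are rounded to 3 decimals, so agreement is to ~1e-3
    assert np.log(1.588) == pytest.approx(0.463, abs=1e-3)


def test_or_ci_brackets_point(rng):
    for _ in range(20):
        est = ivw(random_pairs(rng))
        assert est.ci_low <= est.or_ <= est.ci_high
        assert est.or_ == pytest.approx(np.exp(est.beta))


def test_sign_equivariance(rng):
    """Negating every outcome effect negates every method's estimate."""
    pairs = random_pairs(rng, n=12)
    neg = pairs.copy()
    neg["beta_out"] *= -1
    for fn in (ivw, mr_egger,
               lambda p: weighted_median(p, n_boot=100, seed=0),
               lambda p: mode_estimate(p, n_boot=100, seed=0)):
        assert fn(neg).beta == pytest.approx(-fn(pairs).beta, abs=1e-9)


def test_scale_equivariance(rng):
    """Multiplying all exposure effects by c>0 divides estimates by c."""
    pairs = random_pairs(rng, n=12)
    scaled = pairs.copy()
    scaled[["beta_exp", "se_exp"]] *= 2.5
    for fn in (ivw, mr_egger,
               lambda p: weighted_median(p, n_boot=100, seed=0),
               lambda p: mode_estimate(p, n_boot=100, seed=0)):
        assert fn(scaled).beta == pytest.approx(fn(pairs).beta / 2.5, abs=1e-9)


def test_sklearn_protocol():
    """get_params/set_params/clone round-trip and fitted attributes."""
    from sklearn.base import clone

    est = IVWEstimator(random_effects=False)
    assert clone(est).get_params() == {"random_effects": False}
    est.set_params(random_effects=True)
    pairs = make_pairs([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.11, 0.14], [0.02] * 3)
    fitted = est.fit(pairs)
    for attr in ("beta_", "se_", "pvalue_", "or_", "n_snp_"):
        assert hasattr(fitted, attr)
    assert fitted.predict(pairs) == pytest.approx(fitted.beta_ * pairs["beta_exp"])
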