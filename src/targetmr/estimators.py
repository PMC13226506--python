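"""Two-sample MR causal-effect estimators.

All estimators consume harmonized per-SNP pairs — exposure effect
``beta_exp`` with standard error ``se_exp`` and outcome effect
``beta_out`` with ``se_out`` on a common effect-allele frame — and
follow the scikit-learn estimator protocol: construct with
hyper-parameters, call :meth:`fit` with the pair table, then read the
fitted attributes (``beta_``, ``se_``, ``pvalue_``, ``or_`` ...).

Methods implemented:

* Wald ratio — single-instrument estimate ``beta_out / beta_exp`` with
  first-order standard error ``se_out / |beta_exp|``.
* IVW — inverse-variance-weighted regression of outcome on exposure
  effects through the origin, weights ``1/se_out^2``; the primary method.
  Standard errors use the multiplicative random-effects model: the
  fixed-effect SE is inflated by ``sqrt(Q/(n-1))`` when Cochran's Q
  exceeds its degrees of freedom.
* MR-Egger — the same weighted regression with an unconstrained
  intercept.  The intercept estimates average directional pleiotropy;
  the slope remains a consistent causal estimate under the InSIDE
  assumption.  Exposure effects are oriented positive before fitting so
  the intercept is interpretable; p-values are t-distributed on n-2 df.
* Weighted median — the median of the weighted empirical distribution of
  Wald ratios; consistent when instruments carrying at least half the
  weight are valid.  SE by seeded parametric bootstrap.
* Simple/weighted mode — the argmax of a (weighted) normal-kernel
  density over the Wald ratios, bandwidth ``phi`` times a MAD-based
  modified Silverman rule; consistent when the largest group of
  instruments with equal ratios is valid.  SE by parametric bootstrap.

Estimates are reported on the log-odds scale together with the odds
ratio ``exp(beta)`` and its 95% CI ``exp(beta +/- 1.96 se)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .stats import two_sided_normal_p, two_sided_t_p

__all__ = [
    "MREstimate", "InsufficientInstrumentsError",
    "WaldRatioEstimator", "IVWEstimator", "EggerEstimator",
    "WeightedMedianEstimator", "ModeEstimator",
    "wald_ratio", "ivw", "mr_egger", "weighted_median", "mode_estimate",
    "beta_to_or", "all_methods",
]


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the method's minimum."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "OR": self.or_,
            "CI_low": self.ci_low,
            "CI_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snp": self.n_snp,
        }


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with 95% CI exp(beta +/- 1.96 se)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return float(np.exp(beta)), float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))


def _as_arrays(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Validate a pair table into (beta_exp, se_exp, beta_out, se_out)."""
    if isinstance(X, pd.DataFrame):
        if "action" in X.columns:
            X = X[X["action"].isin(["none", "swapped"])]
        cols = ["beta_exp", "se_exp", "beta_out", "se_out"]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"pair table missing columns {missing}")
        arr = X[cols].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("expected an (n, 4) array of "
                             "(beta_exp, se_exp, beta_out, se_out)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in pair table")
    bx, sx, by, sy = arr.T
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("standard errors must be > 0")
    return bx, sx, by, sy


def _wald_ratios(bx, sx, by, sy) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates and first-order SEs."""
    if np.any(bx == 0):
        raise ZeroDivisionError("beta_exp = 0: Wald ratio undefined")
    return by / bx, sy / np.abs(bx)


class _BaseMR(BaseEstimator):
    """Shared fit plumbing: validation, OR transform, result export."""

    method = "base"
    min_snps = 2

    def _check(self, X):
        bx, sx, by, sy = _as_arrays(X)
        if bx.shape[0] < self.min_snps:
            raise InsufficientInstrumentsError(
                f"{self.method} needs >= {self.min_snps} instruments, "
                f"got {bx.shape[0]}"
            )
        return bx, sx, by, sy

    def _finalize(self, beta, se, pvalue, n_snp):
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.pvalue_ = float(min(pvalue, 1.0))
        self.or_, self.ci_low_, self.ci_high_ = beta_to_or(self.beta_, self.se_)
        self.n_snp_ = int(n_snp)
        return self

    def predict(self, X):
        """Predicted outcome effects beta_ * beta_exp for new pairs."""
        bx = _as_arrays(X)[0]
        return self.beta_ * bx

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method=self.method,
            beta=self.beta_,
            se=self.se_,
            pvalue=self.pvalue_,
            or_=self.or_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            n_snp=self.n_snp_,
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_p=getattr(self, "intercept_p_", None),
        )


class WaldRatioEstimator(_BaseMR):
    """Single-instrument causal estimate beta_out / beta_exp."""

    method = "Wald ratio"
    min_snps = 1

    def fit(self, X, y=None):
        bx, sx, by, sy = self._check(X)
        if bx.shape[0] != 1:
            raise InsufficientInstrumentsError(
                "Wald ratio is the single-instrument path; use IVW for >= 2"
            )
        r, sr = _wald_ratios(bx, sx, by, sy)
        return self._finalize(r[0], sr[0], two_sided_normal_p(r[0] / sr[0]), 1)


class IVWEstimator(_BaseMR):
    """Inverse-variance-weighted estimator (weighted regression through
    the origin), multiplicative random-effects standard errors."""

    method = "Inverse variance weighted"
    min_snps = 2

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y=None):
        bx, sx, by, sy = self._check(X)
        n = bx.shape[0]
        w = 1.0 / sy**2
        sxx = np.sum(w * bx * bx)
        beta = np.sum(w * bx * by) / sxx
        se_fixed = np.sqrt(1.0 / sxx)
        q = np.sum(w * (by - beta * bx) ** 2)
        scale = max(1.0, np.sqrt(q / (n - 1))) if (self.random_effects and n > 1) else 1.0
        se = se_fixed * scale
        self.q_ = float(q)
        self.q_df_ = n - 1
        return self._finalize(beta, se, two_sided_normal_p(beta / se), n)


class EggerEstimator(_BaseMR):
    """MR-Egger: weighted regression with an unconstrained intercept.

    Exposure effects are oriented positive (pair signs flipped as needed)
    before fitting; the intercept then estimates average directional
    pleiotropy.  Slope and intercept p-values use t(n-2).
    """

    method = "MR Egger"
    min_snps = 3

    def fit(self, X, y=None):
        bx, sx, by, sy = self._check(X)
        n = bx.shape[0]
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        w = 1.0 / sy**2
        # closed-form weighted least squares with intercept
        sw = np.sum(w)
        mx = np.sum(w * bx) / sw
        my = np.sum(w * by) / sw
        sxx = np.sum(w * (bx - mx) ** 2)
        if sxx == 0:
            raise ValueError("exposure effects are constant; Egger slope undefined")
        slope = np.sum(w * (bx - mx) * (by - my)) / sxx
        intercept = my - slope * mx
        resid = by - intercept - slope * bx
        q = np.sum(w * resid**2)
        df = n - 2
        scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
        se_slope = np.sqrt(1.0 / sxx) * scale
        se_int = np.sqrt(1.0 / sw + mx**2 / sxx) * scale
        self.q_ = float(q)
        self.q_df_ = df
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_p_ = float(two_sided_t_p(intercept / se_int, df))
        return self._finalize(slope, se_slope, two_sided_t_p(slope / se_slope, df), n)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weighted empirical distribution, linearly interpolated."""
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    below = np.max(np.nonzero(cum < 0.5)[0])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(v[below] + frac * (v[below + 1] - v[below]))


class WeightedMedianEstimator(_BaseMR):
    """Weighted-median MR estimator with parametric-bootstrap SE.

    Consistent when instruments carrying >= 50% of the weight are valid.
    """

    method = "Weighted median"
    min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y=None):
        bx, sx, by, sy = self._check(X)
        n = bx.shape[0]
        r, sr = _wald_ratios(bx, sx, by, sy)
        beta = _weighted_median(r, 1.0 / sr**2)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        bx_b = rng.normal(bx, sx, size=(self.n_boot, n))
        by_b = rng.normal(by, sy, size=(self.n_boot, n))
        for i in range(self.n_boot):
            bxi = bx_b[i]
            bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
            ri = by_b[i] / bxi
            sri = sy / np.abs(bxi)
            boots[i] = _weighted_median(ri, 1.0 / sri**2)
        se = float(np.std(boots, ddof=1))
        return self._finalize(beta, se, two_sided_normal_p(beta / se), n)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of a weighted normal-kernel density over Wald ratios.

    Bandwidth: phi times a modified Silverman rule using the smaller of
    the SD and the (scaled) MAD of the ratios.
    """
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad if mad > 0 else sd) * ratios.shape[0] ** (-1 / 5)
    h = max(1e-8, phi * s)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    w = weights / weights.sum()
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


class ModeEstimator(_BaseMR):
    """Simple or weighted mode-based MR estimator.

    ``weighted=False`` gives the simple mode (equal kernel weights);
    ``weighted=True`` weights kernels by inverse ratio variance.  SE by
    seeded parametric bootstrap.
    """

    min_snps = 3

    def __init__(self, weighted: bool = True, phi: float = 1.0,
                 n_boot: int = 1000, seed: int = 0):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed

    @property
    def method(self):
        return "Weighted mode" if self.weighted else "Simple mode"

    def fit(self, X, y=None):
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        bx, sx, by, sy = self._check(X)
        n = bx.shape[0]
        r, sr = _wald_ratios(bx, sx, by, sy)
        w = 1.0 / sr**2 if self.weighted else np.ones(n)
        beta = _mode_point(r, w, self.phi)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        bx_b = rng.normal(bx, sx, size=(self.n_boot, n))
        by_b = rng.normal(by, sy, size=(self.n_boot, n))
        for i in range(self.n_boot):
            bxi = np.where(bx_b[i] == 0, np.finfo(float).tiny, bx_b[i])
            ri = by_b[i] / bxi
            wi = (np.abs(bxi) / sy) ** 2 if self.weighted else np.ones(n)
            boots[i] = _mode_point(ri, wi, self.phi)
        se = float(np.std(boots, ddof=1))
        return self._finalize(beta, se, two_sided_normal_p(beta / se), n)


# ---------------------------------------------------------------------------
# thin functional wrappers

def wald_ratio(pair) -> MREstimate:
    return WaldRatioEstimator().fit(pair).to_estimate()


def ivw(pairs, random_effects: bool = True) -> MREstimate:
    return IVWEstimator(random_effects=random_effects).fit(pairs).to_estimate()


def mr_egger(pairs) -> MREstimate:
    return EggerEstimator().fit(pairs).to_estimate()


def weighted_median(pairs, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(pairs).to_estimate()


def mode_estimate(pairs, weighted: bool = True, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return ModeEstimator(weighted=weighted, phi=phi, n_boot=n_boot,
                         seed=seed).fit(pairs).to_estimate()


def all_methods(pairs, n_boot: int = 1000, phi: float = 1.0,
                seed: int = 0) -> pd.DataFrame:
    """Run the five-method battery; one row per method.

    Falls back to the Wald ratio when only one pair is available.
    """
    bx = _as_arrays(pairs)[0]
    if bx.shape[0] == 1:
        return pd.DataFrame([wald_ratio(pairs).as_row()])
    ests = [ivw(pairs)]
    if bx.shape[0] >= 3:
        ests += [
            mr_egger(pairs),
            mode_estimate(pairs, weighted=False, phi=phi, n_boot=n_boot, seed=seed),
            weighted_median(pairs, n_boot=n_boot, seed=seed),
            mode_estimate(pairs, weighted=True, phi=phi, n_boot=n_boot, seed=seed),
        ]
    return pd.DataFrame([e.as_row() for e in ests])
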