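"""Heterogeneity, pleiotropy, leave-one-out, and MR-PRESSO diagnostics.

Conventions: Cochran's Q uses outcome-variance weights ``1/se_out^2``
around the fitted IVW (df = n-1) or Egger (df = n-2) model; I^2 is
``max(0, (Q - df)/Q) * 100``; heterogeneity p is the upper-tail
chi-square probability of Q.  Leave-one-out re-runs the primary (IVW)
estimator with each instrument omitted.  MR-PRESSO compares the observed
leave-one-out residual sum of squares against a parametric simulation of
the no-pleiotropy null; empirical p-values use the (r+1)/(n_sim+1)
convention, so they lie in [1/(n_sim+1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerEstimator, IVWEstimator, _as_arrays


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its df, p-value and the I^2 transform."""

    Q: float
    df: int
    pvalue: float
    i2: float  # percent, in [0, 100]


@dataclass
class PleiotropyResult:
    """Horizontal-pleiotropy diagnostics: Egger intercept + MR-PRESSO."""

    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    presso_global_rss: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list = field(default_factory=list)
    presso_outlier_p: dict = field(default_factory=dict)
    presso_distortion_p: float | None = None
    beta_all: float | None = None
    beta_outlier_corrected: float | None = None


def i_squared(Q: float, df: int) -> float:
    """I^2 heterogeneity percentage: max(0, (Q-df)/Q) * 100."""
    if Q < 0 or df < 1:
        raise ValueError("require Q >= 0 and df >= 1")
    if Q == 0:
        return 0.0
    return float(max(0.0, (Q - df) / Q) * 100.0)


def heterogeneity_from_q(Q: float, df: int) -> HeterogeneityResult:
    """Assemble the heterogeneity summary from an already-computed Q."""
    return HeterogeneityResult(
        Q=float(Q), df=int(df),
        pvalue=float(stats.chi2.sf(Q, df)),
        i2=i_squared(Q, df),
    )


def cochran_q(pairs, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q around the IVW (df=n-1) or Egger (df=n-2) fit."""
    method = method.lower()
    if method == "ivw":
        est = IVWEstimator().fit(pairs)
    elif method == "egger":
        est = EggerEstimator().fit(pairs)
    else:
        raise ValueError("method must be 'ivw' or 'egger'")
    q, df = est.q_, est.q_df_
    return HeterogeneityResult(
        Q=float(q), df=int(df),
        pvalue=float(stats.chi2.sf(q, df)),
        i2=i_squared(q, df),
    )


def egger_intercept_test(pairs) -> PleiotropyResult:
    """Directional-pleiotropy test from the MR-Egger intercept.

    Unlike the reported Egger estimate, whose standard errors carry the
    multiplicative random-effects floor, the intercept *test* is the
    plain weighted-regression t-test (residual-scaled SE without the
    floor), which is exactly calibrated under the no-pleiotropy null.
    """
    est = EggerEstimator().fit(pairs)
    sigma = float(np.sqrt(est.q_ / est.q_df_)) if est.q_df_ > 0 else 1.0
    se_plain = est.intercept_se_ / max(1.0, sigma) * sigma
    t = est.intercept_ / se_plain
    return PleiotropyResult(
        egger_intercept=est.intercept_,
        intercept_se=float(se_plain),
        intercept_p=float(2.0 * stats.t.sf(abs(t), est.q_df_)),
    )


def leave_one_out(pairs) -> pd.DataFrame:
    """IVW estimates with each instrument omitted in turn.

    One row per omitted SNP, flagged when the omission flips the sign of
    the estimate or moves it outside the full-set 95% CI.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    n = bx.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    snp_ids = (
        pairs["SNP"].to_numpy()
        if isinstance(pairs, pd.DataFrame) and "SNP" in pairs.columns
        else np.array([f"snp_{j}" for j in range(n)], dtype=object)
    )
    if isinstance(pairs, pd.DataFrame) and "action" in pairs.columns:
        keep = pairs["action"].isin(["none", "swapped"]).to_numpy()
        snp_ids = pairs["SNP"].to_numpy()[keep]
    full = IVWEstimator().fit(np.column_stack([bx, sx, by, sy]))
    lo, hi = full.beta_ - 1.96 * full.se_, full.beta_ + 1.96 * full.se_
    rows = []
    for j in range(n):
        mask = np.arange(n) != j
        est = IVWEstimator().fit(np.column_stack([bx, sx, by, sy])[mask])
        flagged = (np.sign(est.beta_) != np.sign(full.beta_)) or not (
            lo <= est.beta_ <= hi
        )
        rows.append(
            {
                "omitted": snp_ids[j],
                "beta": est.beta_,
                "se": est.se_,
                "pvalue": est.pvalue_,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes for every SNP, O(n) via running sums.

    Works on trailing-axis SNP dimension, so (n_sim, n) arrays broadcast.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    pairs,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PleiotropyResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Global test: the observed residual sum of squares (each SNP's
    outcome effect against the IVW fit of the other SNPs, weighted by
    1/se_out^2) is compared with ``n_sim`` simulated RSS values drawn
    under the no-pleiotropy parametric model.  Outlier test: each SNP's
    observed squared residual against its simulated distribution,
    Bonferroni-corrected at ``outlier_alpha``.  Distortion test: when
    outliers are found, the change in the IVW estimate after their
    removal is compared with removals of random subsets of equal size.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    n = bx.shape[0]
    if n < 4:
        raise ValueError("MR-PRESSO needs >= 4 instruments")
    snp_ids = (
        pairs["SNP"].to_numpy()[pairs["action"].isin(["none", "swapped"]).to_numpy()]
        if isinstance(pairs, pd.DataFrame) and "action" in pairs.columns
        else (
            pairs["SNP"].to_numpy()
            if isinstance(pairs, pd.DataFrame) and "SNP" in pairs.columns
            else np.array([f"snp_{j}" for j in range(n)], dtype=object)
        )
    )
    w = 1.0 / sy**2
    slopes_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    # parametric null: resample both sides around the leave-one-out fit
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, n))
    slopes_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    per_snp_p = (np.sum(resid_sim >= resid_obs[None, :], axis=0) + 1) / (n_sim + 1)
    flagged = per_snp_p * n < outlier_alpha  # Bonferroni
    outliers = [snp_ids[j] for j in np.nonzero(flagged)[0]]

    result = PleiotropyResult(
        presso_global_rss=rss_obs,
        presso_global_p=global_p,
        presso_outliers=outliers,
        presso_outlier_p={snp_ids[j]: float(per_snp_p[j]) for j in range(n)},
    )

    X = np.column_stack([bx, sx, by, sy])
    beta_all = IVWEstimator().fit(X).beta_
    result.beta_all = float(beta_all)
    if outliers and len(outliers) < n - 1:
        keep = ~flagged
        beta_corr = IVWEstimator().fit(X[keep]).beta_
        result.beta_outlier_corrected = float(beta_corr)
        d_obs = (beta_all - beta_corr) / abs(beta_corr)
        n_out = int(flagged.sum())
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(n, size=n_out, replace=False)
            m = np.ones(n, dtype=bool)
            m[drop] = False
            b = IVWEstimator().fit(X[m]).beta_
            d_sim[i] = (beta_all - b) / abs(b)
        result.presso_distortion_p = float(
            (np.sum(np.abs(d_sim) >= abs(d_obs)) + 1) / (n_sim + 1)
        )
    return result


def diagnostics_table(pairs, n_sim: int = 1000, seed: int = 0) -> pd.DataFrame:
    """One-row summary of all sensitivity diagnostics for a pair set."""
    het = cochran_q(pairs, "ivw")
    het_egger = cochran_q(pairs, "egger")
    pleio = egger_intercept_test(pairs)
    presso = mr_presso(pairs, n_sim=n_sim, seed=seed) if len(_as_arrays(pairs)[0]) >= 4 else None
    return pd.DataFrame(
        [
            {
                "I2_pct": het.i2,
                "Q": het.Q,
                "Q_pvalue": het.pvalue,
                "Q_egger": het_egger.Q,
                "Q_egger_pvalue": het_egger.pvalue,
                "egger_intercept": pleio.egger_intercept,
                "egger_intercept_p": pleio.intercept_p,
                "presso_global_p": presso.presso_global_p if presso else np.nan,
                "presso_n_outliers": len(presso.presso_outliers) if presso else 0,
            }
        ]
    )
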