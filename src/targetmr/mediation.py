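"""Two-step mediation MR with mediation-proportion reporting.

The mediated (indirect) effect of an exposure on an outcome through a
mediator trait is estimated as the product of two univariable MR
estimates: beta1 (exposure -> mediator) times beta2 (mediator ->
outcome).  With beta3 the total exposure -> outcome effect from the
primary analysis, the direct effect is beta3 - beta1*beta2 (difference
method) and the proportion mediated is 100 * beta1*beta2 / beta3
percent.  A mediation result is reportable when the total, direct and
indirect effects share a sign and the absolute proportion exceeds 5%.

The proportion's confidence interval is delta-method based, treating
the three estimates as independent normals; a parametric-bootstrap CI is
available as an option.  Multiple mediators are screened with
Benjamini-Hochberg FDR control across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import MREstimate, ivw, wald_ratio
from .harmonize import harmonize, retained
from .instruments import (
    IMMUNE_TRAIT_CRITERIA,
    InstrumentCriteria,
    select_instruments,
)
from .io import SummaryStatSet


@dataclass(frozen=True)
class MediationResult:
    """One mediator's two-step decomposition of the total effect."""

    mediator_id: str
    beta1: float
    beta2: float
    beta3: float
    indirect: float
    direct: float
    proportion: float          # percent of the total effect
    proportion_ci: tuple[float, float]
    reportable: bool
    beta1_p: float | None = None
    beta2_p: float | None = None


def proportion_ci(
    beta1: float, se1: float, beta2: float, se2: float,
    beta3: float, se3: float, level: float = 0.95,
) -> tuple[float, float]:
    """Delta-method CI for the mediated proportion 100*b1*b2/b3 (percent).

    Treats the three estimates as independent normals; the interval is
    symmetric about the point estimate by construction.
    """
    if min(se1, se2, se3) < 0:
        raise ValueError("standard errors must be >= 0")
    if beta3 == 0:
        raise ZeroDivisionError("total effect beta3 = 0: proportion undefined")
    point = 100.0 * beta1 * beta2 / beta3
    g1 = 100.0 * beta2 / beta3
    g2 = 100.0 * beta1 / beta3
    g3 = -100.0 * beta1 * beta2 / beta3**2
    se = np.sqrt((g1 * se1) ** 2 + (g2 * se2) ** 2 + (g3 * se3) ** 2)
    z = float(stats.norm.ppf(1 - (1 - level) / 2))
    return (float(point - z * se), float(point + z * se))


def proportion_ci_bootstrap(
    beta1, se1, beta2, se2, beta3, se3,
    n_boot: int = 10_000, seed: int = 0, level: float = 0.95,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile CI for the mediated proportion."""
    rng = np.random.default_rng(seed)
    b1 = rng.normal(beta1, se1, n_boot)
    b2 = rng.normal(beta2, se2, n_boot)
    b3 = rng.normal(beta3, se3, n_boot)
    props = 100.0 * b1 * b2 / b3
    alpha = (1 - level) / 2
    return (float(np.quantile(props, alpha)), float(np.quantile(props, 1 - alpha)))


def two_step_mediation(
    beta1: MREstimate, beta2: MREstimate, beta3: MREstimate,
    mediator_id: str = "mediator",
) -> MediationResult:
    """Combine step-1, step-2 and total estimates into a mediation result.

    The identity ``beta3 = direct + indirect`` holds exactly because the
    direct effect is computed by difference.
    """
    for est in (beta1, beta2, beta3):
        if not np.isfinite(est.beta):
            raise ValueError("all three estimates must have finite betas")
    if beta3.beta == 0:
        raise ZeroDivisionError("total effect beta3 = 0: proportion undefined")
    indirect = beta1.beta * beta2.beta
    direct = beta3.beta - indirect
    proportion = 100.0 * indirect / beta3.beta
    ci = proportion_ci(beta1.beta, beta1.se, beta2.beta, beta2.se,
                       beta3.beta, beta3.se)
    aligned = (
        indirect != 0
        and np.sign(indirect) == np.sign(beta3.beta) == np.sign(direct)
    )
    return MediationResult(
        mediator_id=mediator_id,
        beta1=beta1.beta,
        beta2=beta2.beta,
        beta3=beta3.beta,
        indirect=indirect,
        direct=direct,
        proportion=proportion,
        proportion_ci=ci,
        reportable=bool(aligned and abs(proportion) > 5.0),
        beta1_p=beta1.pvalue,
        beta2_p=beta2.pvalue,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _uvmr(pairs) -> MREstimate | None:
    """IVW when >= 2 instruments, Wald ratio for exactly one, else None."""
    r = retained(pairs)
    if len(r) == 0:
        return None
    if len(r) == 1:
        return wald_ratio(r)
    return ivw(r)


def screen_mediators(
    exposure_instruments: SummaryStatSet,
    mediator_panel: dict[str, SummaryStatSet],
    outcome: SummaryStatSet,
    total_effect: MREstimate | None = None,
    mediator_criteria: InstrumentCriteria = IMMUNE_TRAIT_CRITERIA,
    ld=None,
    maf_ambiguous_max: float = 0.42,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-step mediation screen over a panel of candidate mediators.

    For each mediator: step 1 estimates the exposure -> mediator effect
    using the exposure's instruments; step 2 estimates the mediator ->
    outcome effect using the mediator's own instruments, selected with
    the immune-trait criteria.  Step p-values are BH-FDR-adjusted across
    the panel; a row is a hit when it is reportable (signs aligned,
    |proportion| > 5%) and both adjusted step p-values clear ``alpha``.
    Mediators with no surviving instruments appear as not-evaluable rows
    rather than being dropped.
    """
    if not mediator_panel:
        raise ValueError("mediator panel is empty")
    if total_effect is None:
        pairs3, _ = harmonize(exposure_instruments, outcome, maf_ambiguous_max)
        total_effect = _uvmr(pairs3)
        if total_effect is None:
            raise ValueError("no instruments survive for the total-effect model")

    rows = []
    for mediator_id, mediator in mediator_panel.items():
        pairs1, _ = harmonize(exposure_instruments, mediator, maf_ambiguous_max)
        est1 = _uvmr(pairs1)
        med_instruments, _ = select_instruments(
            mediator, mediator_criteria, ld=ld, outcome=outcome
        )
        est2 = None
        if len(med_instruments) > 0:
            pairs2, _ = harmonize(med_instruments, outcome, maf_ambiguous_max)
            est2 = _uvmr(pairs2)
        if est1 is None or est2 is None:
            rows.append(
                {
                    "mediator": mediator_id, "evaluable": False,
                    "beta1": np.nan, "beta1_p": np.nan,
                    "beta2": np.nan, "beta2_p": np.nan,
                    "beta3": total_effect.beta,
                    "indirect": np.nan, "direct": np.nan,
                    "proportion_pct": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                    "reportable": False,
                }
            )
            continue
        med = two_step_mediation(est1, est2, total_effect, mediator_id)
        rows.append(
            {
                "mediator": mediator_id, "evaluable": True,
                "beta1": med.beta1, "beta1_p": est1.pvalue,
                "beta2": med.beta2, "beta2_p": est2.pvalue,
                "beta3": med.beta3,
                "indirect": med.indirect, "direct": med.direct,
                "proportion_pct": med.proportion,
                "ci_low": med.proportion_ci[0], "ci_high": med.proportion_ci[1],
                "reportable": med.reportable,
            }
        )

    table = pd.DataFrame(rows)
    evaluable = table["evaluable"].to_numpy()
    for col in ("beta1_p", "beta2_p"):
        adj = np.full(len(table), np.nan)
        if evaluable.any():
            adj[evaluable] = bh_fdr(table.loc[evaluable, col].to_numpy())
        table[col.replace("_p", "_q")] = adj
    table["hit"] = (
        table["reportable"]
        & (table["beta1_q"] < alpha)
        & (table["beta2_q"] < alpha)
    ).fillna(False)
    score = np.fmax(table["beta1_q"], table["beta2_q"]).fillna(np.inf)
    table = (
        table.assign(_score=score)
        .sort_values(["_score", "mediator"], kind="mergesort")
        .drop(columns="_score")
        .reset_index(drop=True)
    )
    return table
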