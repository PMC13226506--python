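"""Synthetic GWAS summary statistics with known causal ground truth.

The generator works entirely at the summary level: no individual genotypes
are simulated.  For each variant *j* with minor-allele frequency
``maf_j`` and study sample size *n*, the standard error of an additive
per-allele effect is modelled as

    se_j = 1 / sqrt(2 * maf_j * (1 - maf_j) * n)

(for binary traits *n* is the effective sample size, since effects are
simulated directly on the log-odds scale).  Observed effects are the true
effects plus Normal(0, se_j^2) noise, independent across SNPs unless LD
blocks are requested, in which case noise within a block is drawn
multivariate normal with pairwise correlation r = sqrt(r2).

The causal chain is exposure -> mediator -> outcome.  Exposure-instrument
SNPs carry true exposure effects gamma_j; the mediator inherits
``beta1 * gamma_j`` and the outcome ``direct * gamma_j + beta2 * beta1 *
gamma_j + alpha_j`` where alpha_j is direct (pleiotropic) SNP->outcome
effect.  A second, disjoint panel of SNPs instruments the mediator alone
(true mediator effects delta_k, outcome effects ``beta2 * delta_k``), so
the second mediation step has its own instruments, as it does in a real
two-step screen.  The ground-truth total effect satisfies
``total = direct + beta1 * beta2`` exactly.

A single integer seed governs all draws; each operation derives its own
deterministic sub-stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SummaryStatSet, records_from_arrays
from .stats import two_sided_normal_p

# sub-stream tags so each operation has an independent deterministic stream
_STREAMS = {"truth": 1, "exposure": 2, "outcome": 3, "mediator": 4, "scramble": 5}

#: non-palindromic effect/other allele pairs used for generated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class CausalScenario:
    """Ground-truth parameters for the generator.

    Defaults mirror the scale of a cis-eQTL drug-target analysis of a
    rare binary outcome: a protective total effect of -0.306 log-odds per
    SD of exposure, partially mediated through an immune trait
    (beta1 = 0.463, beta2 = -0.188, direct = -0.219), with 13 exposure
    instruments of eQTL-scale strength.  ``n_*`` are effective sample
    sizes on the analysis scale.
    """

    n_snps: int = 13
    theta: float = -0.306          # exposure -> outcome total effect (log-odds)
    beta1: float = 0.463           # exposure -> mediator
    beta2: float = -0.188          # mediator -> outcome
    direct: float = -0.219         # direct exposure -> outcome
    gamma_mean: float = 0.061      # SNP -> exposure effect distribution
    gamma_sd: float = 0.01
    pleiotropy_mean: float = 0.0   # direct SNP -> outcome effects
    pleiotropy_sd: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.4)
    n_exp: int = 31684
    n_out: int = 3622
    n_med: int = 3757
    n_snps_mediator: int = 10      # SNPs instrumenting the mediator alone
    delta_mean: float = 0.18       # SNP -> mediator effect for those SNPs
    delta_sd: float = 0.03
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0 or self.delta_sd < 0:
            raise ValueError("sd parameters must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def total_effect(self) -> float:
        """Ground-truth total exposure->outcome effect: direct + beta1*beta2."""
        return self.direct + self.beta1 * self.beta2

    @property
    def proportion_mediated(self) -> float:
        """Ground-truth mediated proportion, percent of the total effect."""
        return 100.0 * self.beta1 * self.beta2 / self.total_effect


@dataclass
class ScenarioTruth:
    """Per-SNP latent truth shared by the exposure/mediator/outcome draws."""

    snp_ids: np.ndarray
    positions: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    maf: np.ndarray
    gamma: np.ndarray              # true SNP->exposure effects
    alpha: np.ndarray              # direct SNP->outcome (pleiotropic) effects
    delta: np.ndarray              # true SNP->mediator effects (mediator panel)
    is_exposure_instrument: np.ndarray
    chromosome: str = "1"

    @property
    def exposure_ids(self) -> np.ndarray:
        return self.snp_ids[self.is_exposure_instrument]


def _rng(scenario: CausalScenario, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed) % (2**31), _STREAMS[stream]])
    )


def _se_model(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _draw_noise(rng, se: np.ndarray, ld_blocks, n_exposure: int) -> np.ndarray:
    """Noise ~ N(0, se^2), correlated within declared LD blocks."""
    z = rng.standard_normal(se.shape[0])
    if ld_blocks:
        pos = 0
        for size, r2 in ld_blocks:
            size = min(size, n_exposure - pos)
            if size <= 0:
                break
            r = float(np.sqrt(r2))
            shared = rng.standard_normal()
            # equicorrelated construction: corr(z_i, z_j) = r within block
            z[pos : pos + size] = (
                np.sqrt(r) * shared + np.sqrt(1.0 - r) * z[pos : pos + size]
            )
            pos += size
    return z * se


def draw_truth(scenario: CausalScenario, include_mediator_panel: bool = False) -> ScenarioTruth:
    """Draw the latent per-SNP truth (MAFs, effects, positions, alleles)."""
    rng = _rng(scenario, "truth")
    n_exp_snps = scenario.n_snps
    n_total = n_exp_snps + (scenario.n_snps_mediator if include_mediator_panel else 0)
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, n_total)
    gamma = np.zeros(n_total)
    gamma[:n_exp_snps] = rng.normal(scenario.gamma_mean, scenario.gamma_sd, n_exp_snps)
    alpha = rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, n_total)
    delta = np.zeros(n_total)
    if include_mediator_panel:
        delta[n_exp_snps:] = rng.normal(
            scenario.delta_mean, scenario.delta_sd, scenario.n_snps_mediator
        )
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_total)]
    # exposure instruments sit in a compact cis region; the mediator panel
    # is placed far away (trans) so cis filtering separates them
    positions = np.where(
        np.arange(n_total) < n_exp_snps,
        5_000_000 + np.arange(n_total) * 10_000,
        150_000_000 + np.arange(n_total) * 2_000_000,
    ).astype(np.int64)
    return ScenarioTruth(
        snp_ids=np.array([f"rs{100000 + j}" for j in range(n_total)], dtype=object),
        positions=positions,
        ea=np.array([p[0] for p in pairs], dtype=object),
        oa=np.array([p[1] for p in pairs], dtype=object),
        maf=maf,
        gamma=gamma,
        alpha=alpha,
        delta=delta,
        is_exposure_instrument=np.arange(n_total) < n_exp_snps,
    )


def _emit(truth: ScenarioTruth, true_beta, n: int, rng, trait_id: str,
          ld_blocks, n_exposure: int, trait_type: str = "continuous") -> SummaryStatSet:
    se = _se_model(truth.maf, n)
    beta_obs = np.asarray(true_beta, dtype=float) + _draw_noise(rng, se, ld_blocks, n_exposure)
    p = two_sided_normal_p(beta_obs / se)
    records = records_from_arrays(
        truth.snp_ids, truth.chromosome, truth.positions, truth.ea, truth.oa,
        truth.maf, beta_obs, se, p, n,
    )
    return SummaryStatSet(trait_id=trait_id, records=records, trait_type=trait_type,
                          n_total=n)


def simulate_exposure_stats(
    scenario: CausalScenario, truth: ScenarioTruth | None = None
) -> tuple[SummaryStatSet, ScenarioTruth]:
    """Summary statistics for the exposure study (cis-eQTL-like).

    Returns the stat set together with the latent truth so that outcome
    and mediator draws (and test assertions) share the same gamma vector.
    Deterministic given ``scenario.seed``.
    """
    if truth is None:
        truth = draw_truth(scenario)
    rng = _rng(scenario, "exposure")
    return (
        _emit(truth, truth.gamma, scenario.n_exp, rng, "exposure",
              scenario.ld_blocks, scenario.n_snps),
        truth,
    )


def simulate_outcome_stats(
    scenario: CausalScenario, truth: ScenarioTruth
) -> SummaryStatSet:
    """Outcome summary statistics: true effects theta*gamma_j + alpha_j."""
    if len(truth.gamma) < scenario.n_snps:
        raise ValueError("exposure truth length does not match scenario")
    true_beta = scenario.theta * truth.gamma + truth.alpha
    rng = _rng(scenario, "outcome")
    return _emit(truth, true_beta, scenario.n_out, rng, "outcome",
                 scenario.ld_blocks, scenario.n_snps, trait_type="binary")


def simulate_mediation_triplet(
    scenario: CausalScenario,
) -> tuple[SummaryStatSet, SummaryStatSet, SummaryStatSet, ScenarioTruth]:
    """Exposure, mediator and outcome summary sets for one causal chain.

    Exposure-instrument SNPs: mediator true effect = beta1*gamma_j and
    outcome true effect = direct*gamma_j + beta2*(beta1*gamma_j) + alpha_j.
    Mediator-panel SNPs: mediator effect delta_k, outcome effect
    beta2*delta_k + alpha_k, zero exposure effect.  The ground-truth
    proportion mediated is ``beta1*beta2 / (direct + beta1*beta2)``.
    """
    truth = draw_truth(scenario, include_mediator_panel=True)
    exp_set, _ = simulate_exposure_stats(scenario, truth)
    med_true = scenario.beta1 * truth.gamma + truth.delta
    out_true = (
        scenario.direct * truth.gamma
        + scenario.beta2 * med_true
        + truth.alpha
    )
    med_rng = _rng(scenario, "mediator")
    out_rng = _rng(scenario, "outcome")
    med_set = _emit(truth, med_true, scenario.n_med, med_rng, "mediator",
                    scenario.ld_blocks, scenario.n_snps)
    out_set = _emit(truth, out_true, scenario.n_out, out_rng, "outcome",
                    scenario.ld_blocks, scenario.n_snps, trait_type="binary")
    return exp_set, med_set, out_set, truth


def simulate_mediation_panel(
    scenario: CausalScenario,
    n_mediators: int = 10,
    true_index: int = 0,
) -> tuple[SummaryStatSet, dict[str, SummaryStatSet], SummaryStatSet, ScenarioTruth]:
    """A mediator screen's worth of summary sets with one true mediator.

    The SNP universe holds the exposure's cis instruments plus a disjoint
    trans panel of ``n_snps_mediator`` instruments per mediator.  Only
    mediator ``true_index`` sits on the causal chain (beta1, beta2 as in
    the scenario); the others have beta1 = 0 but still affect the outcome
    through their own instruments with effect beta2, so they are
    outcome-relevant non-mediators.  All sets cover the full SNP universe,
    as real GWAS extracts would.
    """
    if not (0 <= true_index < n_mediators):
        raise ValueError("true_index out of range")
    n_exp_snps = scenario.n_snps
    k = scenario.n_snps_mediator
    n_total = n_exp_snps + n_mediators * k

    rng = _rng(scenario, "truth")
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, n_total)
    gamma = np.zeros(n_total)
    gamma[:n_exp_snps] = rng.normal(scenario.gamma_mean, scenario.gamma_sd, n_exp_snps)
    alpha = rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, n_total)
    # delta[m, j]: SNP j's true effect on mediator m
    delta = np.zeros((n_mediators, n_total))
    for m in range(n_mediators):
        s = n_exp_snps + m * k
        delta[m, s : s + k] = rng.normal(scenario.delta_mean, scenario.delta_sd, k)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_total)]
    positions = np.where(
        np.arange(n_total) < n_exp_snps,
        5_000_000 + np.arange(n_total) * 10_000,
        150_000_000 + np.arange(n_total) * 2_000_000,
    ).astype(np.int64)
    truth = ScenarioTruth(
        snp_ids=np.array([f"rs{100000 + j}" for j in range(n_total)], dtype=object),
        positions=positions,
        ea=np.array([p[0] for p in pairs], dtype=object),
        oa=np.array([p[1] for p in pairs], dtype=object),
        maf=maf,
        gamma=gamma,
        alpha=alpha,
        delta=delta[true_index],
        is_exposure_instrument=np.arange(n_total) < n_exp_snps,
    )

    beta1 = np.zeros(n_mediators)
    beta1[true_index] = scenario.beta1
    med_true = beta1[:, None] * gamma[None, :] + delta  # (n_mediators, n_total)
    out_true = (
        scenario.direct * gamma
        + scenario.beta2 * med_true.sum(axis=0)
        + alpha
    )

    exp_rng = _rng(scenario, "exposure")
    exp_set = _emit(truth, gamma, scenario.n_exp, exp_rng, "exposure",
                    scenario.ld_blocks, n_exp_snps)
    med_rng = _rng(scenario, "mediator")
    mediators = {
        f"mediator_{m:02d}": _emit(
            truth, med_true[m], scenario.n_med, med_rng, f"mediator_{m:02d}",
            None, n_exp_snps,
        )
        for m in range(n_mediators)
    }
    out_rng = _rng(scenario, "outcome")
    out_set = _emit(truth, out_true, scenario.n_out, out_rng, "outcome",
                    None, n_exp_snps, trait_type="binary")
    return exp_set, mediators, out_set, truth


def scramble_records(
    stat_set: SummaryStatSet,
    swap_fraction: float = 0.0,
    palindrome_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[SummaryStatSet, dict]:
    """Create harmonization test cases by perturbing allele frames.

    A ``swap_fraction`` subset has effect/other alleles exchanged with the
    beta negated and EAF complemented (an equivalent representation of
    the same association); a disjoint-where-possible ``palindrome_fraction``
    subset is rewritten onto A/T or C/G allele pairs.  Returns the new set
    and a truth log with the affected SNP ids.
    """
    if not (0 <= swap_fraction <= 1 and 0 <= palindrome_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31),
                                                        _STREAMS["scramble"]]))
    df = stat_set.records.copy()
    n = len(df)
    n_swap = int(round(swap_fraction * n))
    n_pal = int(round(palindrome_fraction * n))
    order = rng.permutation(n)
    swap_idx = np.sort(order[:n_swap])
    pal_idx = np.sort(order[max(n - n_pal, 0):])

    if n_pal:
        pal_pairs = [("A", "T"), ("C", "G")]
        choice = rng.integers(0, 2, len(pal_idx))
        flip = rng.integers(0, 2, len(pal_idx)).astype(bool)
        ea = np.array([pal_pairs[c][int(f)] for c, f in zip(choice, flip)], dtype=object)
        oa = np.array([pal_pairs[c][1 - int(f)] for c, f in zip(choice, flip)], dtype=object)
        df.loc[df.index[pal_idx], "EA"] = ea
        df.loc[df.index[pal_idx], "OA"] = oa
    if n_swap:
        rows = df.index[swap_idx]
        ea = df.loc[rows, "EA"].copy()
        df.loc[rows, "EA"] = df.loc[rows, "OA"].values
        df.loc[rows, "OA"] = ea.values
        df.loc[rows, "BETA"] = -df.loc[rows, "BETA"]
        df.loc[rows, "EAF"] = 1.0 - df.loc[rows, "EAF"]

    log = {
        "swapped": df.loc[df.index[swap_idx], "SNP"].tolist(),
        "palindromic": df.loc[df.index[pal_idx], "SNP"].tolist(),
    }
    return replace(stat_set, records=df), log


def inject_outlier(
    outcome: SummaryStatSet, snp_id: str, multiplier: float
) -> SummaryStatSet:
    """Multiply one SNP's outcome beta, leaving everything else unchanged."""
    df = outcome.records.copy()
    hit = df["SNP"] == snp_id
    if not hit.any():
        raise KeyError(f"unknown SNP {snp_id!r}")
    df.loc[hit, "BETA"] *= multiplier
    return replace(outcome, records=df)


class BlockLDProvider:
    """Pairwise r-squared provider matching the generator's LD blocks.

    SNPs are assigned to blocks in panel order; pairs within a block share
    the block's r2, pairs across blocks have r2 = 0.
    """

    def __init__(self, truth: ScenarioTruth, ld_blocks):
        self._block = {}
        self._r2 = {}
        pos = 0
        for b, (size, r2) in enumerate(ld_blocks or []):
            for snp in truth.snp_ids[pos : pos + size]:
                self._block[snp] = b
                self._r2[b] = float(r2)
            pos += size

    def __call__(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        ba, bb = self._block.get(snp_a), self._block.get(snp_b)
        if ba is None or bb is None or ba != bb:
            return 0.0
        return self._r2[ba]
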