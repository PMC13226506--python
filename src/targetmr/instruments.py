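"""Instrument selection for drug-target and immune-trait exposures.

Each filter is a pure subset operation on a :class:`SummaryStatSet`:
output records are a subset of the input records and no field is mutated.
The default pipeline order is cis-window -> significance -> LD clumping ->
MAF/palindrome -> blocklist -> outcome-association exclusion, but every
filter is order-independent in its own contract.

Two named criteria presets are provided, matching common practice for
drug-target cis-eQTL instruments (p < 1e-5, r2 < 0.30 within 100 kb,
MAF > 0.05, cis window +/-300 kb) and for immune-cell trait instruments
(p < 1e-5, r2 < 0.001 within 10,000 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .io import SummaryStatSet

#: pairwise r-squared provider signature: (snp_id_a, snp_id_b) -> r2 in [0, 1]
LDProvider = Callable[[str, str], float]


@dataclass(frozen=True)
class InstrumentCriteria:
    """Thresholds governing instrument selection."""

    p_threshold: float = 1e-5
    r2_threshold: float = 0.30
    clump_window_kb: float = 100.0
    maf_min: float = 0.05
    maf_ambiguous_max: float = 0.42
    cis_window_kb: float | None = 300.0   # None = no cis restriction
    outcome_p_exclusion: float = 1e-5
    f_min: float = 10.0

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be > 0")
        if self.cis_window_kb is not None and self.cis_window_kb <= 0:
            raise ValueError("cis_window_kb must be > 0")


#: preset for cis-eQTL drug-target instruments
DRUG_TARGET_CRITERIA = InstrumentCriteria()

#: preset for immune-cell trait instruments (no cis restriction)
IMMUNE_TRAIT_CRITERIA = InstrumentCriteria(
    r2_threshold=0.001, clump_window_kb=10_000.0, cis_window_kb=None
)

PRESETS = {"drug-target": DRUG_TARGET_CRITERIA, "immune-trait": IMMUNE_TRAIT_CRITERIA}


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic interval, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("locus start must be <= end")


def filter_cis_window(
    stat_set: SummaryStatSet, locus: GeneLocus, window_kb: float
) -> SummaryStatSet:
    """Keep SNPs on the locus chromosome within +/- window of its bounds."""
    window = int(round(window_kb * 1000))
    df = stat_set.records
    mask = (
        (df["CHR"].astype(str) == str(locus.chromosome))
        & (df["POS"] >= locus.start - window)
        & (df["POS"] <= locus.end + window)
    )
    return stat_set.subset(mask.to_numpy())


def filter_significance(stat_set: SummaryStatSet, p_threshold: float) -> SummaryStatSet:
    """Keep records with p-value strictly below the threshold."""
    return stat_set.subset((stat_set.records["P"] < p_threshold).to_numpy())


def clump(
    stat_set: SummaryStatSet,
    ld: LDProvider,
    r2_threshold: float,
    window_kb: float,
) -> SummaryStatSet:
    """Greedy LD clumping by ascending p-value.

    Repeatedly keep the smallest-p remaining SNP and discard all remaining
    SNPs within ``window_kb`` of it whose pairwise r2 with it is >= the
    threshold.  Ties on p-value break lexicographically on snp_id, so the
    result is deterministic.  The output is ordered by ascending p.
    """
    df = stat_set.records
    order = df.sort_values(["P", "SNP"], kind="mergesort").index.to_list()
    window = window_kb * 1000.0
    kept: list[int] = []
    alive = set(order)
    for idx in order:
        if idx not in alive:
            continue
        kept.append(idx)
        alive.discard(idx)
        row = df.loc[idx]
        for other in list(alive):
            o = df.loc[other]
            if (
                str(o["CHR"]) == str(row["CHR"])
                and abs(int(o["POS"]) - int(row["POS"])) <= window
                and ld(str(row["SNP"]), str(o["SNP"])) >= r2_threshold
            ):
                alive.discard(other)
    out = stat_set.subset(np.isin(df.index.to_numpy(), kept))
    return _reorder_by_p(out)


def _reorder_by_p(stat_set: SummaryStatSet) -> SummaryStatSet:
    from dataclasses import replace

    recs = stat_set.records.sort_values(["P", "SNP"], kind="mergesort").reset_index(
        drop=True
    )
    return replace(stat_set, records=recs)


def filter_maf(
    stat_set: SummaryStatSet, maf_min: float, maf_ambiguous_max: float = 0.42
) -> SummaryStatSet:
    """MAF filter plus the palindrome-ambiguity drop rule.

    Removes records with MAF = min(EAF, 1-EAF) <= ``maf_min``; also
    removes palindromic records (A/T, C/G) with MAF > ``maf_ambiguous_max``
    — at such frequencies allele frequency cannot resolve the strand.
    Records with missing EAF fail closed (removed).
    """
    df = stat_set.records
    maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
    palindromic = _palindromic_mask(df)
    keep = (maf > maf_min) & ~(palindromic & (maf > maf_ambiguous_max))
    keep &= df["EAF"].notna()
    return stat_set.subset(keep.to_numpy())


def _palindromic_mask(df: pd.DataFrame) -> pd.Series:
    pair = df["EA"].astype(str) + df["OA"].astype(str)
    return pair.isin(["AT", "TA", "CG", "GC"])


def per_snp_f(beta: float, se: float) -> float:
    """Per-SNP instrument strength: the Wald chi-square (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def f_statistics(stat_set: SummaryStatSet) -> pd.Series:
    """Per-SNP F statistics for a whole set, indexed by snp_id."""
    df = stat_set.records
    return pd.Series(
        (df["BETA"] / df["SE"]) ** 2, index=df["SNP"].to_numpy(), name="F"
    )


def filter_strength(stat_set: SummaryStatSet, f_min: float = 10.0) -> SummaryStatSet:
    """Keep instruments with per-SNP F above the adequacy bound."""
    f = ((stat_set.records["BETA"] / stat_set.records["SE"]) ** 2).to_numpy()
    return stat_set.subset(f > f_min)


def exclude_outcome_associated(
    instruments: SummaryStatSet,
    outcome: SummaryStatSet,
    p_cut: float = 1e-5,
) -> tuple[SummaryStatSet, list[str]]:
    """Drop instruments directly associated with the outcome (p < cut).

    Instruments absent from the outcome set are unmatchable for the MR and
    are also removed; their ids are returned separately.
    """
    out_p = outcome.records.set_index("SNP")["P"]
    snp = instruments.records["SNP"]
    matched = snp.isin(out_p.index)
    unmatched = snp[~matched].tolist()
    assoc = snp.map(out_p).lt(p_cut).fillna(False)
    keep = matched & ~assoc
    return instruments.subset(keep.to_numpy()), unmatched


def apply_blocklist(
    instruments: SummaryStatSet, blocklist: Iterable[str], log: list | None = None
) -> SummaryStatSet:
    """Remove listed SNPs (e.g. confounder-associated variants from a
    trait-lookup screen), logging each removal."""
    block = set(blocklist)
    removed = [s for s in instruments.records["SNP"] if s in block]
    if log is not None:
        log.extend(f"blocklist removed {s}" for s in removed)
    out = instruments.subset((~instruments.records["SNP"].isin(block)).to_numpy())
    if len(out) == 0 and len(instruments) > 0:
        import warnings

        warnings.warn("blocklist removed every instrument", stacklevel=2)
    return out


def read_blocklist(path) -> list[str]:
    """One SNP id per line; blank lines and #-comments ignored."""
    out = []
    for line in open(path):
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def select_instruments(
    exposure: SummaryStatSet,
    criteria: InstrumentCriteria,
    ld: LDProvider | None = None,
    locus: GeneLocus | None = None,
    blocklist: Iterable[str] = (),
    outcome: SummaryStatSet | None = None,
) -> tuple[SummaryStatSet, dict[str, int]]:
    """Run the full selection cascade; returns survivors and stage counts."""
    counts = {"input": len(exposure)}
    current = exposure
    if locus is not None and criteria.cis_window_kb is not None:
        current = filter_cis_window(current, locus, criteria.cis_window_kb)
        counts["cis_window"] = len(current)
    current = filter_significance(current, criteria.p_threshold)
    counts["significance"] = len(current)
    if ld is not None:
        current = clump(current, ld, criteria.r2_threshold, criteria.clump_window_kb)
        counts["clump"] = len(current)
    current = filter_maf(current, criteria.maf_min, criteria.maf_ambiguous_max)
    counts["maf"] = len(current)
    current = apply_blocklist(current, blocklist)
    counts["blocklist"] = len(current)
    if outcome is not None:
        current, unmatched = exclude_outcome_associated(
            current, outcome, criteria.outcome_p_exclusion
        )
        counts["outcome_exclusion"] = len(current)
        counts["unmatched_in_outcome"] = len(unmatched)
    current = filter_strength(current, criteria.f_min)
    counts["strength"] = len(current)
    return current, counts
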