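"""Place exposure and outcome statistics on a common effect-allele frame.

For each SNP shared by the two sets the outcome record is reconciled to
the exposure's allele frame:

* identical alleles — kept as-is;
* swapped alleles (outcome EA == exposure OA and vice versa) — outcome
  beta negated and EAF complemented;
* palindromic alleles (A/T or C/G) — strand cannot be read off the
  alleles, so orientation falls back to allele frequency: pairs where
  either side's MAF exceeds the ambiguity cutoff are dropped, otherwise
  the frequencies orient the strand (both EAF on the same side of 0.5
  means same strand; disagreement means the outcome is strand-flipped
  and its beta is negated);
* incompatible allele sets — dropped as mismatches.

Alleles are taken at face value after a reverse-complement check; no
strand inference from genomic context is attempted.  Multi-allelic
variants and indels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SummaryStatSet

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of the harmonized-pair table
PAIR_COLUMNS = [
    "SNP", "EA", "OA", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "action",
]

ACTIONS = ("none", "swapped", "dropped_palindromic", "dropped_mismatch")


@dataclass
class HarmonizeReport:
    """Conservation bookkeeping for a harmonization pass."""

    n_shared: int = 0
    n_retained: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0
    n_exposure_only: int = 0
    n_outcome_only: int = 0
    dropped_ids: list = field(default_factory=list)

    def check_conservation(self) -> bool:
        return (
            self.n_retained
            + self.n_dropped_palindromic
            + self.n_dropped_mismatch
            == self.n_shared
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    maf_ambiguous_max: float = 0.42,
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Harmonize outcome statistics onto the exposure's allele frame.

    Returns a pair table (one row per shared SNP, including dropped rows
    with their ``action`` audit value) and a conservation report.
    Retained rows have ``action`` in {"none", "swapped"}.
    """
    exp = exposure.records.set_index("SNP")
    out = outcome.records.set_index("SNP")
    shared = exp.index.intersection(out.index)
    report = HarmonizeReport(
        n_shared=len(shared),
        n_exposure_only=len(exp.index.difference(out.index)),
        n_outcome_only=len(out.index.difference(exp.index)),
    )

    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = str(e["EA"]), str(e["OA"])
        ea_o, oa_o = str(o["EA"]), str(o["OA"])
        beta_out, eaf_out = float(o["BETA"]), float(o["EAF"])

        if _is_palindromic(ea_e, oa_e):
            action = _resolve_palindrome(
                e, o, maf_ambiguous_max
            )
            if action == "dropped_palindromic":
                report.n_dropped_palindromic += 1
                report.dropped_ids.append(snp)
                rows.append(_row(snp, e, beta_out, o, eaf_out, action))
                continue
            if action == "flipped":
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = "swapped"
        elif (ea_o, oa_o) == (ea_e, oa_e):
            action = "none"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            action = "swapped"
        elif (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)) == (ea_e, oa_e):
            action = "none"  # strand-flipped representation, same orientation
        elif (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)) == (oa_e, ea_e):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            action = "swapped"
        else:
            action = "dropped_mismatch"
            report.n_dropped_mismatch += 1
            report.dropped_ids.append(snp)
            rows.append(_row(snp, e, beta_out, o, eaf_out, action))
            continue

        report.n_retained += 1
        rows.append(_row(snp, e, beta_out, o, eaf_out, action))

    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs, report


def _resolve_palindrome(e, o, maf_ambiguous_max: float) -> str:
    """Orient a palindromic pair by allele frequency, or drop it."""
    eaf_e, eaf_o = float(e["EAF"]), float(o["EAF"])
    if np.isnan(eaf_e) or np.isnan(eaf_o):
        return "dropped_palindromic"
    maf_e = min(eaf_e, 1 - eaf_e)
    maf_o = min(eaf_o, 1 - eaf_o)
    if maf_e > maf_ambiguous_max or maf_o > maf_ambiguous_max:
        return "dropped_palindromic"
    same_side = (eaf_e < 0.5) == (eaf_o < 0.5)
    return "none" if same_side else "flipped"


def _row(snp, e, beta_out, o, eaf_out, action):
    return (
        snp, str(e["EA"]), str(e["OA"]),
        float(e["BETA"]), float(e["SE"]),
        beta_out, float(o["SE"]),
        float(e["EAF"]), eaf_out,
        action,
    )


def retained(pairs: pd.DataFrame) -> pd.DataFrame:
    """The analysable subset of a harmonized-pair table."""
    return pairs[pairs["action"].isin(["none", "swapped"])].reset_index(drop=True)


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Serialize a harmonized-pair table (with the action audit column)."""
    pairs.to_csv(path, sep="\t", index=False, float_format="%.17g")
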