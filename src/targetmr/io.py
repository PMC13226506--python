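"""Read, validate and write GWAS summary-statistic tables.

The canonical on-disk dialect is a tab-separated file with columns
``SNP CHR POS EA OA EAF BETA SE P N`` (1-based inclusive coordinates).
Alternate headers — e.g. TwoSampleMR-style exposure/outcome extracts —
are supported through a column-mapping config (YAML/JSON or a plain dict
mapping canonical names to file headers).

Records are validated row by row: alleles must be single uppercase
nucleotides and distinct, standard errors positive, p-values in (0, 1],
allele frequencies in [0, 1].  Rows failing validation are rejected and
reported with their row numbers rather than silently dropped.  EAF may be
missing on read (flagged); such records cannot pass MAF-based filters
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: canonical column order of the on-disk dialect
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_VALID_ALLELES = frozenset("ACGT")


class SummaryStatFormatError(ValueError):
    """A structural problem with a summary-statistic file (missing columns etc.)."""


@dataclass(frozen=True)
class SNPRecord:
    """One variant's summary-association statistics for one trait.

    ``beta`` is the per-effect-allele additive effect: log-odds for binary
    traits, SD units for continuous traits.
    """

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.effect_allele not in _VALID_ALLELES:
            problems.append(f"effect allele {self.effect_allele!r} not one of A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            problems.append(f"other allele {self.other_allele!r} not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect and other allele identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append(f"eaf {self.eaf} outside [0, 1]")
        if not np.isfinite(self.beta):
            problems.append("beta not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            problems.append(f"se {self.se} not > 0")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append(f"pvalue {self.pvalue} outside (0, 1]")
        if self.n <= 0:
            problems.append(f"n {self.n} not positive")
        return problems

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency min(EAF, 1-EAF); None when EAF is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G allele pairs (strand-ambiguous)."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryStatSet:
    """A trait's GWAS summary statistics: metadata plus a table of records.

    The record table uses the canonical columns; ``snp_id`` is unique
    within the set.
    """

    trait_id: str
    records: pd.DataFrame
    trait_type: str = "continuous"  # binary | continuous
    ancestry: str = "European"
    n_total: int | None = None
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if list(self.records.columns) != CANONICAL_COLUMNS:
            missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
            if missing:
                raise SummaryStatFormatError(f"record table missing columns {missing}")
            self.records = self.records[CANONICAL_COLUMNS]
        if self.records["SNP"].duplicated().any():
            dups = self.records.loc[self.records["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate snp_id within set: {dups[:5]}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, mask_or_ids) -> "SummaryStatSet":
        """New set with a row subset; metadata preserved, fields untouched."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(
            mask_or_ids
        ) == len(self.records) and pd.api.types.is_bool_dtype(
            np.asarray(mask_or_ids)
        ):
            recs = self.records.loc[np.asarray(mask_or_ids)]
        else:
            recs = self.records[self.records["SNP"].isin(set(mask_or_ids))]
        return replace(self, records=recs.reset_index(drop=True))

    def to_records(self) -> list[SNPRecord]:
        out = []
        for row in self.records.itertuples(index=False):
            eaf = None if pd.isna(row.EAF) else float(row.EAF)
            out.append(
                SNPRecord(
                    snp_id=str(row.SNP),
                    chromosome=str(row.CHR),
                    position=int(row.POS),
                    effect_allele=str(row.EA),
                    other_allele=str(row.OA),
                    eaf=eaf,
                    beta=float(row.BETA),
                    se=float(row.SE),
                    pvalue=float(row.P),
                    n=int(row.N),
                )
            )
        return out


@dataclass
class ReadReport:
    """Bookkeeping from a table read: accepted/rejected row accounting."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)
    missing_eaf_rows: list[int] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _load_mapping(dialect) -> dict[str, str]:
    """Resolve a column-mapping config into {canonical: file header}."""
    if dialect is None:
        return {c: c for c in CANONICAL_COLUMNS}
    if isinstance(dialect, Mapping):
        mapping = dict(dialect)
    else:
        text = Path(dialect).read_text()
        mapping = (
            json.loads(text) if str(dialect).endswith(".json") else yaml.safe_load(text)
        )
    out = {c: c for c in CANONICAL_COLUMNS}
    out.update({k: v for k, v in mapping.items() if k in CANONICAL_COLUMNS})
    return out


def read_summary_table(
    path,
    dialect=None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    ancestry: str = "European",
    n_total: int | None = None,
    n_cases: int | None = None,
) -> tuple[SummaryStatSet, ReadReport]:
    """Read a summary-statistic TSV into a validated :class:`SummaryStatSet`.

    Parameters
    ----------
    path : file path
    dialect : mapping, path to YAML/JSON mapping, or None
        Maps canonical column names to the file's headers.
    trait_id, trait_type, ancestry, n_total, n_cases
        Trait metadata (e.g. from a study table: "Cervical cancer,
        239,158 total, 909 cases" gives ``n_total=239158, n_cases=909``).

    Returns
    -------
    (SummaryStatSet, ReadReport)
        Rejected rows are listed in the report with 1-based data-row
        numbers and the reason.
    """
    path = Path(path)
    mapping = _load_mapping(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [m for c, m in mapping.items() if m not in raw.columns]
    if missing:
        raise SummaryStatFormatError(
            f"{path}: mapped columns absent from file: {missing}"
        )
    raw = raw.rename(columns={v: k for k, v in mapping.items()})[CANONICAL_COLUMNS]

    report = ReadReport(n_rows=len(raw))
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        try:
            eaf = None if pd.isna(row.EAF) or row.EAF == "" else float(row.EAF)
            rec = SNPRecord(
                snp_id=str(row.SNP),
                chromosome=str(row.CHR),
                position=int(float(row.POS)),
                effect_allele=str(row.EA).upper(),
                other_allele=str(row.OA).upper(),
                eaf=eaf,
                beta=float(row.BETA),
                se=float(row.SE),
                pvalue=float(row.P),
                n=int(float(row.N)),
            )
        except (TypeError, ValueError) as exc:
            report.rejected.append((i, f"non-numeric field: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            report.rejected.append((i, "; ".join(problems)))
            continue
        if rec.eaf is None:
            report.missing_eaf_rows.append(i)
        rows.append(
            (
                rec.snp_id,
                rec.chromosome,
                rec.position,
                rec.effect_allele,
                rec.other_allele,
                np.nan if rec.eaf is None else rec.eaf,
                rec.beta,
                rec.se,
                rec.pvalue,
                rec.n,
            )
        )
    report.n_accepted = len(rows)
    records = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    if records.empty:
        records = _empty_records()
    stat_set = SummaryStatSet(
        trait_id=trait_id or path.stem,
        records=records,
        trait_type=trait_type,
        ancestry=ancestry,
        n_total=n_total,
        n_cases=n_cases,
    )
    return stat_set, report


def write_summary_table(stat_set: SummaryStatSet, path) -> Path:
    """Write a set as canonical TSV; lossless roundtrip at float precision."""
    path = Path(path)
    df = stat_set.records.copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": pd.Series(dtype=str),
            "CHR": pd.Series(dtype=str),
            "POS": pd.Series(dtype=np.int64),
            "EA": pd.Series(dtype=str),
            "OA": pd.Series(dtype=str),
            "EAF": pd.Series(dtype=float),
            "BETA": pd.Series(dtype=float),
            "SE": pd.Series(dtype=float),
            "P": pd.Series(dtype=float),
            "N": pd.Series(dtype=np.int64),
        }
    )


def records_from_arrays(
    snp_ids: Sequence[str],
    chromosome,
    position,
    effect_allele,
    other_allele,
    eaf,
    beta,
    se,
    pvalue,
    n,
) -> pd.DataFrame:
    """Assemble a canonical record table from aligned arrays."""
    return pd.DataFrame(
        {
            "SNP": np.asarray(snp_ids, dtype=object),
            "CHR": np.broadcast_to(np.asarray(chromosome, dtype=object), (len(snp_ids),)).copy(),
            "POS": np.asarray(position, dtype=np.int64),
            "EA": np.asarray(effect_allele, dtype=object),
            "OA": np.asarray(other_allele, dtype=object),
            "EAF": np.asarray(eaf, dtype=float),
            "BETA": np.asarray(beta, dtype=float),
            "SE": np.asarray(se, dtype=float),
            "P": np.asarray(pvalue, dtype=float),
            "N": np.broadcast_to(np.asarray(n, dtype=np.int64), (len(snp_ids),)).copy(),
        }
    )
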