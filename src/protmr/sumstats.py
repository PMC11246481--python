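"""Summary-statistic containers, I/O and allele harmonization.

GWAS and pQTL summary statistics arrive as delimited tables with one row per
variant (rsID, chromosome, position, effect/other allele, effect-allele
frequency, beta, SE, p, sample size).  This module validates such tables into
:class:`SumStats`, writes them back out, and aligns the effect alleles of an
exposure (protein level) file with an outcome (disease) file so that betas
refer to the same allele -- flipping signs for swapped alleles and dropping
strand-ambiguous palindromic variants.

Conventions
-----------
* Positions are 1-based, inclusive.
* Alleles are single characters in {A, C, G, T}; anything else is rejected.
* Protein betas are in SD units per allele; binary-trait betas are log-odds.
* Palindromic variants (A/T or C/G) are dropped when the effect-allele
  frequency is missing or within ``0.5 +/- eaf_window`` on either side;
  outside the window strand is inferred from frequency concordance.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AssocRecord",
    "TraitMeta",
    "SumStats",
    "HarmonizedPair",
    "ConfigurationError",
    "EmptyInputError",
    "read_sumstats",
    "write_sumstats",
    "read_trait_meta",
    "write_trait_meta",
    "harmonize",
    "kept_pairs",
    "CANONICAL_COLUMNS",
]


class ConfigurationError(ValueError):
    """A required column or configuration entry could not be resolved."""


class EmptyInputError(ValueError):
    """An input file contained no usable rows."""


VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical TSV header -> internal field name
CANONICAL_COLUMNS: Mapping[str, str] = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
    "N_CASES": "n_cases",
}

MANDATORY_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one trait: identity, type and sample sizes."""

    trait_id: str
    trait_type: str  # "continuous" or "binary"
    n: int
    n_cases: int | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous/binary, got {self.trait_type!r}")
        if self.n <= 0:
            raise ValueError("sample size must be positive")
        if self.trait_type == "binary":
            if self.n_cases is None:
                raise ValueError("binary traits require n_cases")
            if not 0 < self.n_cases <= self.n:
                raise ValueError("n_cases must be in (0, n]")


@dataclass(frozen=True)
class AssocRecord:
    """Per-SNP association summary for one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1]")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be single characters in ACGT")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.pos <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive (1-based)")

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


def _qc_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    """Drop rows violating the AssocRecord invariants; tally reasons."""
    tally: Counter = Counter()
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    def flag(mask: pd.Series, reason: str) -> pd.Series:
        tally[reason] += int(mask.sum())
        return mask

    bad = flag(~(df["se"] > 0) | ~np.isfinite(df["se"]), "invalid_se")
    bad |= flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "invalid_pval")
    if "eaf" in df.columns:
        eaf = pd.to_numeric(df["eaf"], errors="coerce")
        bad |= flag(eaf.notna() & ~((eaf >= 0) & (eaf <= 1)), "invalid_eaf")
    allele_ok = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(VALID_ALLELES)
    bad |= flag(~allele_ok, "invalid_alleles")
    bad |= flag(allele_ok & (df["effect_allele"] == df["other_allele"]), "identical_alleles")
    bad |= flag(~(pd.to_numeric(df["pos"], errors="coerce") > 0), "invalid_pos")
    dup = df["snp_id"].duplicated(keep="first")
    bad |= flag(dup & ~bad, "duplicate_snp")
    tally = Counter({k: v for k, v in tally.items() if v})
    return df.loc[~bad].reset_index(drop=True), tally


@dataclass
class SumStats:
    """Validated per-SNP summary statistics for one trait.

    ``df`` uses internal column names (``snp_id``, ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``,
    ``n``, ``n_cases``); ``snp_id`` is unique.
    """

    meta: TraitMeta
    df: pd.DataFrame
    qc_tally: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        for col in MANDATORY_FIELDS:
            if col not in self.df.columns:
                raise ConfigurationError(f"missing mandatory column {col!r}")
        if self.df["snp_id"].duplicated().any():
            raise ValueError("snp_id must be unique within a SumStats")
        if "eaf" not in self.df.columns:
            self.df = self.df.assign(eaf=np.nan)
        if "n" not in self.df.columns or self.df["n"].isna().all():
            self.df = self.df.assign(n=self.meta.n)
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: TraitMeta) -> "SumStats":
        clean, tally = _qc_frame(df)
        return cls(meta=meta, df=clean, qc_tally=tally)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[AssocRecord]:
        for row in self.df.itertuples(index=False):
            yield AssocRecord(
                snp_id=row.snp_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=int(row.n) if not pd.isna(row.n) else None,
                n_cases=int(row.n_cases)
                if "n_cases" in self.df.columns and not pd.isna(getattr(row, "n_cases", np.nan))
                else None,
            )

    def subset(self, mask) -> "SumStats":
        return replace(self, df=self.df.loc[mask].reset_index(drop=True), qc_tally=Counter())


def read_sumstats(
    path: str | Path,
    meta: TraitMeta,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> SumStats:
    """Read a delimited summary-statistics table into a validated SumStats.

    ``column_map`` maps file headers onto the canonical header set
    {SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N, N_CASES} for dialects whose
    headers differ; the canonical set is assumed when omitted.  Rows violating
    the per-record invariants are dropped and counted in ``qc_tally``.
    """
    raw = pd.read_csv(path, sep=sep, dtype={"SNP": str, "CHR": str})
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [
        h
        for h, f in CANONICAL_COLUMNS.items()
        if f in MANDATORY_FIELDS and h not in raw.columns
    ]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}")
    df = raw.rename(columns=dict(CANONICAL_COLUMNS))
    df = df[[c for c in CANONICAL_COLUMNS.values() if c in df.columns]]
    ss = SumStats.from_frame(df, meta)
    if ss.n_records == 0:
        raise EmptyInputError(f"{path}: no valid rows after QC (dropped: {dict(ss.qc_tally)})")
    return ss


def write_sumstats(ss: SumStats, path: str | Path, sep: str = "\t") -> None:
    """Write a SumStats back to the canonical TSV layout (round-trips)."""
    inv = {v: k for k, v in CANONICAL_COLUMNS.items()}
    out = ss.df.rename(columns=inv)
    cols = [k for k in CANONICAL_COLUMNS if k in out.columns]
    out[cols].to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_trait_meta(meta: TraitMeta, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta.__dict__, indent=1, sort_keys=True) + "\n")


def read_trait_meta(path: str | Path) -> TraitMeta:
    return TraitMeta(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP expressed on the same allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    eaf_exp: float | None
    beta_out: float
    se_out: float
    pval_out: float
    flipped: bool = False
    dropped_reason: str = "none"  # none | palindromic_ambiguous | allele_mismatch


PAIR_COLUMNS = [
    "snp_id",
    "beta_exp",
    "se_exp",
    "pval_exp",
    "eaf_exp",
    "beta_out",
    "se_out",
    "pval_out",
    "flipped",
    "dropped_reason",
]


def harmonize(
    exposure: SumStats, outcome: SumStats, eaf_window: float = 0.08
) -> pd.DataFrame:
    """Align outcome effect alleles to the exposure's; one row per shared SNP.

    For each SNP present in both traits: matching alleles are kept as-is;
    swapped alleles flip the outcome beta sign and complement the outcome EAF;
    palindromic variants with missing EAF or EAF within ``0.5 +/- eaf_window``
    (either trait) are dropped as strand-ambiguous, otherwise aligned by
    frequency; anything else is an allele mismatch.  Dropped rows stay in the
    output with a ``dropped_reason`` so the attrition is auditable;
    :func:`kept_pairs` filters to usable rows.
    """
    merged = exposure.df.merge(
        outcome.df, on="snp_id", suffixes=("_exp", "_out"), how="inner"
    )
    rows = []
    for r in merged.itertuples(index=False):
        ea_e, oa_e = r.effect_allele_exp, r.other_allele_exp
        ea_o, oa_o = r.effect_allele_out, r.other_allele_out
        eaf_e = None if pd.isna(r.eaf_exp) else float(r.eaf_exp)
        eaf_o = None if pd.isna(r.eaf_out) else float(r.eaf_out)
        palindromic = COMPLEMENT[ea_e] == oa_e
        flipped = False
        reason = "none"
        beta_out = float(r.beta_out)

        if palindromic:
            ambiguous = (
                eaf_e is None
                or eaf_o is None
                or abs(eaf_e - 0.5) <= eaf_window
                or abs(eaf_o - 0.5) <= eaf_window
            )
            if {ea_o, oa_o} != {ea_e, oa_e}:
                reason = "allele_mismatch"
            elif ambiguous:
                reason = "palindromic_ambiguous"
            else:
                # strand/orientation by frequency: the exposure effect allele
                # and the outcome effect allele agree iff their frequencies
                # fall on the same side of 0.5
                flipped = (eaf_e < 0.5) != (eaf_o < 0.5)
        elif (ea_o, oa_o) == (ea_e, oa_e):
            flipped = False
        elif (ea_o, oa_o) == (oa_e, ea_e):
            flipped = True
        else:
            reason = "allele_mismatch"

        if flipped:
            beta_out = -beta_out
            if eaf_o is not None:
                eaf_o = 1.0 - eaf_o
        rows.append(
            (
                r.snp_id,
                float(r.beta_exp),
                float(r.se_exp),
                float(r.pval_exp),
                eaf_e,
                beta_out,
                float(r.se_out),
                float(r.pval_out),
                flipped,
                reason,
            )
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def kept_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonization result usable for estimation."""
    return pairs.loc[pairs["dropped_reason"] == "none"].reset_index(drop=True)
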