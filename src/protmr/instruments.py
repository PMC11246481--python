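"""cis-pQTL instrument selection and strength diagnostics.

Instruments for a protein are its cis variants: within 1 Mb of the encoding
gene, genome-wide significant (p < 5e-8), outside the MHC region
(chr6:26-34 Mb, where extreme LD and pleiotropy make instruments unreliable),
and mutually independent after greedy LD clumping at r^2 < 0.001.  Per-SNP
variance explained uses the summary-data pseudo-R^2

    R^2 = Z^2 / (Z^2 + n - 2),      Z = beta / se,

which needs only the association Z score and the sample size; for binary
traits it is applied on the observed scale as a documented approximation.
The first-stage strength diagnostic is

    F = (R^2 / (1 - R^2)) * (n - k - 1) / k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStats

__all__ = [
    "GeneAnnotation",
    "LDMatrix",
    "InstrumentSet",
    "InstrumentParams",
    "cis_filter",
    "significance_filter",
    "mhc_exclude",
    "clump",
    "variance_explained",
    "variance_explained_eaf",
    "f_statistic",
    "select_instruments",
    "read_annotations",
    "write_annotations",
]

MHC_CHROM = "6"
MHC_START = 26_000_000
MHC_END = 34_000_000


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic bounds (1-based, inclusive) of the gene encoding a protein."""

    protein_id: str
    gene_symbol: str
    chrom: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.protein_id}: gene_start > gene_end")


@dataclass
class LDMatrix:
    """Squared-correlation matrix keyed by SNP identifier."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("LD r^2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float:
        """r^2 between two SNPs; SNPs absent from the panel are treated as
        independent (r^2 = 0)."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=[str(s) for s in df.columns], r2=df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass(frozen=True)
class InstrumentParams:
    """Selection thresholds; defaults are the pipeline's canonical criteria."""

    window_bp: int = 1_000_000
    alpha: float = 5e-8
    clump_r2: float = 0.001
    mhc_chrom: str = MHC_CHROM
    mhc_start: int = MHC_START
    mhc_end: int = MHC_END


@dataclass
class InstrumentSet:
    """Clumped cis instruments for one protein with per-SNP R^2 and F."""

    protein_id: str
    records: pd.DataFrame
    r2_explained: np.ndarray = field(default_factory=lambda: np.empty(0))
    f_stat: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_snps(self) -> int:
        return len(self.records)

    @property
    def total_r2(self) -> float:
        return float(min(np.sum(self.r2_explained), 1.0 - 1e-12))


def cis_filter(pqtl: SumStats, gene: GeneAnnotation, window_bp: int = 1_000_000) -> SumStats:
    """Keep variants on the gene's chromosome within ``window_bp`` of its bounds."""
    lo = gene.gene_start - window_bp
    hi = gene.gene_end + window_bp
    df = pqtl.df
    mask = (df["chrom"].astype(str) == str(gene.chrom)) & (df["pos"] >= lo) & (df["pos"] <= hi)
    return pqtl.subset(mask)


def significance_filter(s: SumStats, alpha: float = 5e-8) -> SumStats:
    """Keep genome-wide significant variants (p strictly below ``alpha``)."""
    return s.subset(s.df["pval"] < alpha)


def mhc_exclude(
    s: SumStats,
    chrom: str = MHC_CHROM,
    start_bp: int = MHC_START,
    end_bp: int = MHC_END,
) -> SumStats:
    """Remove variants inside the MHC zone (bounds inclusive)."""
    df = s.df
    inside = (df["chrom"].astype(str) == str(chrom)) & (df["pos"] >= start_bp) & (df["pos"] <= end_bp)
    return s.subset(~inside)


def clump(s: SumStats, ld: LDMatrix, r2_threshold: float = 0.001) -> SumStats:
    """Greedy LD clumping.

    Repeatedly take the remaining variant with the smallest p (ties broken by
    smaller genomic position), emit it, and discard every remaining variant in
    LD (r^2 >= threshold) with any emitted variant.  Output is pairwise
    independent at the threshold and deterministic.
    """
    df = s.df
    order = df.sort_values(["pval", "pos"], kind="mergesort").index.tolist()
    kept: list[int] = []
    for idx in order:
        snp = df.at[idx, "snp_id"]
        if all(ld.r2_between(snp, df.at[k, "snp_id"]) < r2_threshold for k in kept):
            kept.append(idx)
    keep_mask = df.index.isin(kept)
    return s.subset(pd.Series(keep_mask, index=df.index))


def variance_explained(beta: float, se: float, n: int) -> float:
    """Summary-data pseudo-R^2, Z^2/(Z^2 + n - 2)."""
    if n < 4:
        raise ValueError("variance_explained requires n >= 4")
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def variance_explained_eaf(beta: float, eaf: float, trait_sd: float = 1.0) -> float:
    """Frequency-based alternative, 2 f (1-f) beta^2 / sd^2 (not the default)."""
    if not 0 < eaf < 1:
        raise ValueError("eaf must be in (0, 1)")
    return 2 * eaf * (1 - eaf) * beta**2 / trait_sd**2


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """First-stage F from variance explained: (r2/(1-r2)) * (n-k-1)/k."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if k < 1 or n <= k + 1:
        raise ValueError("need k >= 1 and n > k + 1")
    return (r2 / (1 - r2)) * (n - k - 1) / k


def select_instruments(
    pqtl: SumStats,
    gene: GeneAnnotation,
    ld: LDMatrix,
    params: InstrumentParams = InstrumentParams(),
) -> InstrumentSet:
    """cis filter -> significance filter -> MHC exclusion -> LD clumping,
    then per-SNP R^2 and F.  An empty set is returned (not an error) when no
    variant survives; the protein is then skipped downstream."""
    s = cis_filter(pqtl, gene, params.window_bp)
    s = significance_filter(s, params.alpha)
    s = mhc_exclude(s, params.mhc_chrom, params.mhc_start, params.mhc_end)
    s = clump(s, ld, params.clump_r2)
    if s.n_records == 0:
        return InstrumentSet(protein_id=gene.protein_id, records=s.df)
    n_vec = s.df["n"].fillna(pqtl.meta.n).astype(int).to_numpy()
    r2 = np.array(
        [
            variance_explained(b, e, n)
            for b, e, n in zip(s.df["beta"], s.df["se"], n_vec)
        ]
    )
    f = np.array([f_statistic(r, int(n), 1) for r, n in zip(r2, n_vec)])
    return InstrumentSet(protein_id=gene.protein_id, records=s.df, r2_explained=r2, f_stat=f)


def read_annotations(path) -> dict[str, GeneAnnotation]:
    """Gene annotation TSV {PROTEIN_ID, GENE, CHR, START, END} -> dict."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.PROTEIN_ID)] = GeneAnnotation(
            protein_id=str(r.PROTEIN_ID),
            gene_symbol=str(r.GENE),
            chrom=str(r.CHR),
            gene_start=int(r.START),
            gene_end=int(r.END),
        )
    return out


def write_annotations(genes: dict[str, GeneAnnotation], path) -> None:
    rows = [
        (g.protein_id, g.gene_symbol, g.chrom, g.gene_start, g.gene_end)
        for g in genes.values()
    ]
    pd.DataFrame(rows, columns=["PROTEIN_ID", "GENE", "CHR", "START", "END"]).to_csv(
        path, sep="\t", index=False
    )
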