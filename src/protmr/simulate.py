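"""Synthetic LD-structured pQTL / outcome GWAS summary statistics.

Summary statistics are simulated directly -- no individual-level genotypes --
which is sufficient to exercise every pipeline stage at desk scale.  Each
protein gets one cis region of ``snps_per_region`` variants with
block-diagonal exchangeable LD (correlation ``ld_rho`` within blocks of
``ld_block_size``, zero across).  Per SNP j with effect-allele frequency
f_j ~ U(0.05, 0.95):

* exposure SE: 1 / sqrt(2 f_j (1 - f_j) n_exposure)  (protein in SD units)
* outcome SE: the same with the effective case-control sample size
  n_eff = 4 / (1/n_cases + 1/n_controls), the standard approximation for
  heavily imbalanced binary GWAS
* marginal effect means are the LD projection R b of the joint (causal)
  effects, and observed betas are one multivariate-normal draw with
  covariance D R D (D = diag of SEs)

Under a shared-causal configuration the outcome's joint effects are
``theta`` times the exposure's (plus optional pleiotropy on a fraction of
SNPs); under a distinct-causal configuration the outcome gets its own causal
variants, disjoint from the exposure's.  Default cohort shapes mirror the
study design the pipeline targets: a 7213-sample discovery proteomics panel,
a 35559-sample replication panel, and a 275,911-sample outcome GWAS with
16,328 cases.

The ground truth (causal indices, joint effects, theta, shared/distinct flag)
fully determines the expected estimands, so parameter recovery, type-I error,
directionality and colocalization behaviour are all testable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import GeneAnnotation, LDMatrix, write_annotations, read_annotations
from .sumstats import (
    SumStats,
    TraitMeta,
    read_sumstats,
    read_trait_meta,
    write_sumstats,
    write_trait_meta,
)

__all__ = [
    "SimulationConfig",
    "RegionTruth",
    "SyntheticStudy",
    "simulate_ld",
    "make_region_truth",
    "simulate_pqtl",
    "simulate_outcome",
    "simulate_study",
    "simulate_replication",
    "effective_sample_size",
    "save_study",
    "load_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic run; the seed is mandatory."""

    seed: int
    n_proteins: int = 55
    n_causal_proteins: int = 5
    snps_per_region: int = 100
    ld_block_size: int = 10
    ld_rho: float = 0.8
    n_causal_snps: int = 2
    n_exposure: int = 7213
    n_outcome: int = 275_911
    n_cases: int = 16_328
    n_exposure_rep: int = 35_559
    n_outcome_rep: int = 275_911
    n_cases_rep: int = 16_328
    causal_effect_theta: float = 0.3
    pqtl_effect_b: float = 0.15
    target_pqtl_z: float | None = None
    shared_causal: bool = True
    pleiotropy_frac: float = 0.0
    maf_low: float = 0.05
    maf_high: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        for name in (
            "n_proteins",
            "snps_per_region",
            "ld_block_size",
            "n_exposure",
            "n_outcome",
            "n_cases",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must be in [0, 1]")


def effective_sample_size(n: int, n_cases: int) -> float:
    """4 / (1/cases + 1/controls): the usual case-control effective n."""
    n_controls = n - n_cases
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("need positive case and control counts")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def _block_correlation(n_snps: int, block_size: int, rho: float) -> np.ndarray:
    """Block-diagonal exchangeable correlation matrix (signed r)."""
    r = np.eye(n_snps)
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        r[start:stop, start:stop] = rho
    np.fill_diagonal(r, 1.0)
    return r


def simulate_ld(n_snps: int, block_size: int, rho: float, seed: int | None = None) -> LDMatrix:
    """LD (r^2) matrix of the block structure: rho^2 within blocks, 0 across.

    Deterministic given its arguments; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    r = _block_correlation(n_snps, block_size, rho)
    snp_ids = [f"rs{j + 1}" for j in range(n_snps)]
    return LDMatrix(snp_ids=snp_ids, r2=r**2)


@dataclass
class RegionTruth:
    """Ground truth for one protein's cis region."""

    protein_id: str
    snp_ids: list[str]
    chrom: str
    positions: np.ndarray
    eaf: np.ndarray
    causal_idx_exposure: np.ndarray
    b_joint: np.ndarray  # per-allele exposure effects (SD units)
    causal_idx_outcome: np.ndarray
    g_joint: np.ndarray  # per-allele outcome effects (log-odds)
    theta: float
    shared: bool
    is_causal_protein: bool


def make_region_truth(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    protein_id: str,
    chrom: str,
    region_start: int,
    causal_protein: bool,
    prefix: str = "rs",
) -> RegionTruth:
    """Draw frequencies, pick causal variants and set joint effects."""
    m = cfg.snps_per_region
    snp_ids = [f"{prefix}{j + 1}" for j in range(m)]
    positions = region_start + 1000 * np.arange(m)
    eaf = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    se_exp = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * cfg.n_exposure)

    # spread exposure causal variants across distinct LD blocks so clumping
    # retains more than one instrument
    n_blocks = int(np.ceil(m / cfg.ld_block_size))
    k = min(cfg.n_causal_snps, n_blocks)
    blocks = rng.choice(n_blocks, size=k, replace=False)
    causal_exp = np.array(
        sorted(int(b) * cfg.ld_block_size + int(rng.integers(0, min(cfg.ld_block_size, m - b * cfg.ld_block_size))) for b in blocks)
    )
    b_joint = np.zeros(m)
    if cfg.target_pqtl_z is not None:
        b_joint[causal_exp] = cfg.target_pqtl_z * se_exp[causal_exp]
    else:
        b_joint[causal_exp] = cfg.pqtl_effect_b

    theta = cfg.causal_effect_theta if causal_protein else 0.0
    g_joint = np.zeros(m)
    if cfg.shared_causal:
        causal_out = causal_exp.copy()
        g_joint = theta * b_joint
    else:
        # distinct outcome causal variants in blocks free of exposure signal
        free_blocks = np.array([b for b in range(n_blocks) if b not in set(blocks)])
        if free_blocks.size == 0 or not causal_protein:
            causal_out = np.empty(0, dtype=int)
        else:
            chosen = rng.choice(free_blocks, size=min(k, free_blocks.size), replace=False)
            causal_out = np.array(
                sorted(int(b) * cfg.ld_block_size + int(rng.integers(0, min(cfg.ld_block_size, m - b * cfg.ld_block_size))) for b in chosen)
            )
            g_joint[causal_out] = cfg.causal_effect_theta * (
                cfg.target_pqtl_z * se_exp[causal_out]
                if cfg.target_pqtl_z is not None
                else cfg.pqtl_effect_b
            )
    if cfg.pleiotropy_frac > 0:
        n_pleio = int(round(cfg.pleiotropy_frac * m))
        if n_pleio:
            pleio = rng.choice(m, size=n_pleio, replace=False)
            g_joint = g_joint.copy()
            g_joint[pleio] += rng.normal(0.0, 0.02, size=n_pleio)
    return RegionTruth(
        protein_id=protein_id,
        snp_ids=snp_ids,
        chrom=chrom,
        positions=positions,
        eaf=eaf,
        causal_idx_exposure=causal_exp,
        b_joint=b_joint,
        causal_idx_outcome=causal_out,
        g_joint=g_joint,
        theta=theta,
        shared=cfg.shared_causal,
        is_causal_protein=causal_protein,
    )


def _draw_marginal(
    rng: np.random.Generator,
    joint: np.ndarray,
    eaf: np.ndarray,
    n_eff: float,
    corr: np.ndarray,
    block_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One MVN draw of marginal betas: mean R b, covariance D R D."""
    se = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * n_eff)
    mean = corr @ joint
    m = len(eaf)
    z = rng.standard_normal(m)
    noise = np.empty(m)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        sub = corr[start:stop, start:stop]
        chol = np.linalg.cholesky(sub)
        noise[start:stop] = chol @ z[start:stop]
    beta = mean + se * noise
    return beta, se


def _to_sumstats(
    truth: RegionTruth,
    beta: np.ndarray,
    se: np.ndarray,
    meta: TraitMeta,
) -> SumStats:
    from scipy import stats as sps

    z = beta / se
    pval = 2.0 * sps.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": truth.snp_ids,
            "chrom": truth.chrom,
            "pos": truth.positions,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": truth.eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": meta.n,
        }
    )
    if meta.trait_type == "binary":
        df["n_cases"] = meta.n_cases
    return SumStats(meta=meta, df=df)


def simulate_pqtl(
    cfg: SimulationConfig,
    truth: RegionTruth,
    rng: np.random.Generator,
    meta: TraitMeta | None = None,
) -> SumStats:
    """One protein's cis pQTL summary statistics for one cohort."""
    meta = meta or TraitMeta(
        trait_id=truth.protein_id, trait_type="continuous", n=cfg.n_exposure
    )
    corr = _block_correlation(cfg.snps_per_region, cfg.ld_block_size, cfg.ld_rho)
    beta, se = _draw_marginal(rng, truth.b_joint, truth.eaf, meta.n, corr, cfg.ld_block_size)
    return _to_sumstats(truth, beta, se, meta)


def simulate_outcome(
    cfg: SimulationConfig,
    truth: RegionTruth,
    rng: np.random.Generator,
    meta: TraitMeta | None = None,
) -> SumStats:
    """Outcome (binary GWAS) summary statistics over the same region."""
    meta = meta or TraitMeta(
        trait_id="outcome",
        trait_type="binary",
        n=cfg.n_outcome,
        n_cases=cfg.n_cases,
    )
    n_eff = effective_sample_size(meta.n, meta.n_cases)
    corr = _block_correlation(cfg.snps_per_region, cfg.ld_block_size, cfg.ld_rho)
    beta, se = _draw_marginal(rng, truth.g_joint, truth.eaf, n_eff, corr, cfg.ld_block_size)
    return _to_sumstats(truth, beta, se, meta)


@dataclass
class SyntheticStudy:
    """A full simulated study: per-protein pQTLs, one outcome GWAS, LD, truth."""

    cfg: SimulationConfig
    annotations: dict[str, GeneAnnotation]
    pqtl: dict[str, SumStats]
    outcome: SumStats
    ld: dict[str, LDMatrix]
    truth: dict[str, RegionTruth]
    pqtl_replication: dict[str, SumStats] | None = None
    outcome_replication: SumStats | None = None

    @property
    def causal_proteins(self) -> list[str]:
        return [p for p, t in self.truth.items() if t.is_causal_protein]


# 22 autosomes, skipping chromosome 6 so synthetic regions never collide with
# the MHC exclusion zone unless a test plants one there deliberately
_CHROMS = [str(c) for c in range(1, 23) if c != 6]


def simulate_study(cfg: SimulationConfig, outcome_id: str = "BCC") -> SyntheticStudy:
    """Simulate every protein region plus one genome-wide binary outcome."""
    rng = np.random.default_rng(cfg.seed)
    annotations: dict[str, GeneAnnotation] = {}
    pqtls: dict[str, SumStats] = {}
    lds: dict[str, LDMatrix] = {}
    truths: dict[str, RegionTruth] = {}
    outcome_frames = []
    outcome_meta = TraitMeta(
        trait_id=outcome_id, trait_type="binary", n=cfg.n_outcome, n_cases=cfg.n_cases
    )
    causal_flags = np.zeros(cfg.n_proteins, dtype=bool)
    causal_flags[: cfg.n_causal_proteins] = True
    for i in range(cfg.n_proteins):
        pid = f"PROT{i + 1:03d}"
        chrom = _CHROMS[i % len(_CHROMS)]
        region_start = 5_000_000 + 10_000_000 * (i // len(_CHROMS))
        truth = make_region_truth(
            cfg,
            rng,
            protein_id=pid,
            chrom=chrom,
            region_start=region_start,
            causal_protein=bool(causal_flags[i]),
            prefix=f"rs{i + 1:03d}_",
        )
        span = 1000 * (cfg.snps_per_region - 1)
        annotations[pid] = GeneAnnotation(
            protein_id=pid,
            gene_symbol=f"GENE{i + 1}",
            chrom=chrom,
            gene_start=region_start,
            gene_end=region_start + span,
        )
        exp_meta = TraitMeta(trait_id=pid, trait_type="continuous", n=cfg.n_exposure)
        pqtls[pid] = simulate_pqtl(cfg, truth, rng, exp_meta)
        ld = simulate_ld(cfg.snps_per_region, cfg.ld_block_size, cfg.ld_rho)
        lds[pid] = LDMatrix(snp_ids=list(truth.snp_ids), r2=ld.r2)
        truths[pid] = truth
        outcome_frames.append(simulate_outcome(cfg, truth, rng, outcome_meta).df)
    outcome = SumStats(meta=outcome_meta, df=pd.concat(outcome_frames, ignore_index=True))
    return SyntheticStudy(
        cfg=cfg,
        annotations=annotations,
        pqtl=pqtls,
        outcome=outcome,
        ld=lds,
        truth=truths,
    )


def simulate_replication(study: SyntheticStudy, seed_offset: int = 1) -> SyntheticStudy:
    """Fresh cohort draws from the same ground truth: an independent
    replication pQTL panel and an independent outcome GWAS."""
    cfg = study.cfg
    rng = np.random.default_rng((cfg.seed + seed_offset) % 2**31)
    rep_pqtl: dict[str, SumStats] = {}
    outcome_frames = []
    rep_outcome_meta = TraitMeta(
        trait_id=study.outcome.meta.trait_id + "_rep",
        trait_type="binary",
        n=cfg.n_outcome_rep,
        n_cases=cfg.n_cases_rep,
    )
    for pid, truth in study.truth.items():
        exp_meta = TraitMeta(trait_id=pid, trait_type="continuous", n=cfg.n_exposure_rep)
        rep_pqtl[pid] = simulate_pqtl(cfg, truth, rng, exp_meta)
        outcome_frames.append(simulate_outcome(cfg, truth, rng, rep_outcome_meta).df)
    rep_outcome = SumStats(meta=rep_outcome_meta, df=pd.concat(outcome_frames, ignore_index=True))
    return replace(study, pqtl_replication=rep_pqtl, outcome_replication=rep_outcome)


def _truth_to_json(truth: RegionTruth) -> dict:
    d = asdict(truth)
    for key in ("positions", "eaf", "causal_idx_exposure", "b_joint", "causal_idx_outcome", "g_joint"):
        d[key] = np.asarray(d[key]).tolist()
    return d


def _truth_from_json(d: dict) -> RegionTruth:
    return RegionTruth(
        protein_id=d["protein_id"],
        snp_ids=list(d["snp_ids"]),
        chrom=d["chrom"],
        positions=np.asarray(d["positions"], dtype=int),
        eaf=np.asarray(d["eaf"], dtype=float),
        causal_idx_exposure=np.asarray(d["causal_idx_exposure"], dtype=int),
        b_joint=np.asarray(d["b_joint"], dtype=float),
        causal_idx_outcome=np.asarray(d["causal_idx_outcome"], dtype=int),
        g_joint=np.asarray(d["g_joint"], dtype=float),
        theta=float(d["theta"]),
        shared=bool(d["shared"]),
        is_causal_protein=bool(d["is_causal_protein"]),
    )


def _write_pqtl_table(pqtls: dict[str, SumStats], path: Path) -> None:
    frames = []
    for pid, ss in pqtls.items():
        df = ss.df.copy()
        df.insert(0, "PROTEIN", pid)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    from .sumstats import CANONICAL_COLUMNS

    inv = {v: k for k, v in CANONICAL_COLUMNS.items()}
    combined = combined.rename(columns=inv)
    cols = ["PROTEIN"] + [k for k in CANONICAL_COLUMNS if k in combined.columns]
    combined[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def _read_pqtl_table(path: Path, meta_by_protein: dict[str, TraitMeta]) -> dict[str, SumStats]:
    from .sumstats import CANONICAL_COLUMNS

    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "PROTEIN": str})
    df = df.rename(columns=dict(CANONICAL_COLUMNS))
    out = {}
    for pid, sub in df.groupby("PROTEIN", sort=False):
        out[str(pid)] = SumStats(
            meta=meta_by_protein[str(pid)],
            df=sub.drop(columns=["PROTEIN"]).reset_index(drop=True),
        )
    return out


def planted_evidence_flags(study: SyntheticStudy) -> dict[tuple[str, str], dict]:
    """External-validation flags implied by the ground truth: causal proteins
    carry supportive pleiotropy-check and TWAS flags, null proteins none."""
    outcome_id = study.outcome.meta.trait_id
    return {
        (pid, outcome_id): {
            "cause_pass": t.is_causal_protein,
            "twas_pass": t.is_causal_protein,
            "ppi_drug_link": False,
        }
        for pid, t in study.truth.items()
    }


def save_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Persist a study as plain TSV/JSON; same seed gives byte-identical files."""
    outdir = Path(outdir)
    (outdir / "ld").mkdir(parents=True, exist_ok=True)
    _write_pqtl_table(study.pqtl, outdir / "pqtl.tsv")
    write_sumstats(study.outcome, outdir / "outcome.tsv")
    write_trait_meta(study.outcome.meta, outdir / "outcome_meta.json")
    write_annotations(study.annotations, outdir / "annotations.tsv")
    for pid, ld in study.ld.items():
        ld.write_tsv(outdir / "ld" / f"{pid}.tsv")
    truth_json = {pid: _truth_to_json(t) for pid, t in study.truth.items()}
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    cfg_d = asdict(study.cfg)
    (outdir / "sim_config.json").write_text(json.dumps(cfg_d, indent=1, sort_keys=True))
    flags = planted_evidence_flags(study)
    rows = [
        (pid, out, f["cause_pass"], f["twas_pass"], f["ppi_drug_link"])
        for (pid, out), f in flags.items()
    ]
    pd.DataFrame(
        rows, columns=["PROTEIN", "OUTCOME", "CAUSE_PASS", "TWAS_PASS", "PPI_DRUG_LINK"]
    ).to_csv(outdir / "evidence_flags.tsv", sep="\t", index=False)
    if study.pqtl_replication is not None:
        _write_pqtl_table(study.pqtl_replication, outdir / "pqtl_replication.tsv")
    if study.outcome_replication is not None:
        write_sumstats(study.outcome_replication, outdir / "outcome_replication.tsv")
        write_trait_meta(study.outcome_replication.meta, outdir / "outcome_replication_meta.json")


def load_study(outdir: str | Path) -> SyntheticStudy:
    outdir = Path(outdir)
    cfg = SimulationConfig(**json.loads((outdir / "sim_config.json").read_text()))
    truth_json = json.loads((outdir / "truth.json").read_text())
    truths = {pid: _truth_from_json(d) for pid, d in truth_json.items()}
    annotations = read_annotations(outdir / "annotations.tsv")
    metas = {
        pid: TraitMeta(trait_id=pid, trait_type="continuous", n=cfg.n_exposure)
        for pid in truths
    }
    pqtls = _read_pqtl_table(outdir / "pqtl.tsv", metas)
    outcome_meta = read_trait_meta(outdir / "outcome_meta.json")
    outcome = read_sumstats(outdir / "outcome.tsv", outcome_meta)
    lds = {pid: LDMatrix.read_tsv(outdir / "ld" / f"{pid}.tsv") for pid in truths}
    study = SyntheticStudy(
        cfg=cfg,
        annotations=annotations,
        pqtl=pqtls,
        outcome=outcome,
        ld=lds,
        truth=truths,
    )
    rep_path = outdir / "pqtl_replication.tsv"
    if rep_path.exists():
        rep_metas = {
            pid: TraitMeta(trait_id=pid, trait_type="continuous", n=cfg.n_exposure_rep)
            for pid in truths
        }
        study.pqtl_replication = _read_pqtl_table(rep_path, rep_metas)
        rep_meta = read_trait_meta(outdir / "outcome_replication_meta.json")
        study.outcome_replication = read_sumstats(outdir / "outcome_replication.tsv", rep_meta)
    return study
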