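"""Pipeline orchestration: discovery -> sensitivity -> replication/meta ->
colocalization -> grading.

Every threshold any stage uses lives in :class:`PipelineConfig` (no hidden
constants): the cis window, the genome-wide significance level, the clumping
r^2, the MHC zone, the FDR level, the Steiger level, the heterogeneity
boundary, the colocalization priors and pass bar, and the replication level.
Multiple outcomes are handled as independent runs with separate per-outcome
FDR families.  A run manifest records the config hash and seed; two runs with
equal hashes produce equal tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from .coloc import ColocPriors, ColocRegion, coloc_pass, coloc_posteriors
from .direction import steiger_test
from .grading import EvidenceRecord, build_report, read_evidence_flags
from .instruments import InstrumentParams, select_instruments
from .meta import StudyEstimate, meta_auto, replication_pass
from .mr import bh_fdr, cochran_q, ivw_from_pairs, to_or, wald_ratio
from .simulate import SyntheticStudy, load_study
from .sumstats import SumStats, harmonize, kept_pairs

__all__ = [
    "PipelineConfig",
    "run_discovery",
    "run_replication",
    "run_coloc",
    "run_grading",
    "run_full",
    "write_report_bundle",
]

log = logging.getLogger("protmr")


@dataclass
class PipelineConfig:
    """All thresholds and input locations for one pipeline run."""

    # inputs (a study directory in the layout save_study writes, or None to
    # simulate in-memory with sim_* settings)
    study_dir: str | None = None
    evidence_flags: str | None = None
    outdir: str = "results"
    seed: int = 0

    # instrument selection
    cis_window_bp: int = 1_000_000
    gwas_alpha: float = 5e-8
    clump_r2: float = 0.001
    mhc_chrom: str = "6"
    mhc_start: int = 26_000_000
    mhc_end: int = 34_000_000

    # harmonization / estimation
    eaf_window: float = 0.08
    fdr_alpha: float = 0.05
    fdr_family_m: int | None = None
    steiger_alpha: float = 0.05

    # replication / meta
    replication_alpha: float = 0.05
    i2_threshold: float = 0.5

    # colocalization
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_w_continuous: float = coloc_mod.DEFAULT_W_CONTINUOUS
    coloc_w_binary: float = coloc_mod.DEFAULT_W_BINARY
    pph4_pass: float = 0.8  # inclusive stand-alone coloc pass
    tier1_pph4: float = 0.8  # strict bar inside the tier rules
    require_cause: bool = True

    def instrument_params(self) -> InstrumentParams:
        return InstrumentParams(
            window_bp=self.cis_window_bp,
            alpha=self.gwas_alpha,
            clump_r2=self.clump_r2,
            mhc_chrom=self.mhc_chrom,
            mhc_start=self.mhc_start,
            mhc_end=self.mhc_end,
        )

    def coloc_priors(self) -> ColocPriors:
        return ColocPriors(p1=self.coloc_p1, p2=self.coloc_p2, p12=self.coloc_p12)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


DISCOVERY_COLUMNS = [
    "PROTEIN",
    "OUTCOME",
    "METHOD",
    "NSNP",
    "BETA",
    "SE",
    "OR",
    "CI_LOW",
    "CI_HIGH",
    "P",
    "FDR_Q",
    "Q",
    "Q_DF",
    "Q_P",
    "F_MIN",
    "R2_EXP",
    "R2_OUT",
    "STEIGER_P",
    "STEIGER_PASS",
    "NEG_LOG10_P",
    "SIGNIFICANT",
]


def _estimate_for_protein(pqtl, gene, ld, outcome, cfg):
    """Instruments + harmonization + Wald/IVW + heterogeneity for one protein.

    Returns None (with an info log) when the protein yields no usable
    instrument after selection and harmonization.
    """
    inst = select_instruments(pqtl, gene, ld, cfg.instrument_params())
    if inst.n_snps == 0:
        log.info("%s: no instruments after selection; skipped", gene.protein_id)
        return None
    inst_ss = SumStats(meta=pqtl.meta, df=inst.records.copy())
    pairs = kept_pairs(harmonize(inst_ss, outcome, eaf_window=cfg.eaf_window))
    if len(pairs) == 0:
        log.info("%s: no harmonizable instruments; skipped", gene.protein_id)
        return None
    if len(pairs) == 1:
        r = pairs.iloc[0]
        est = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
        q = q_df = q_p = None
    else:
        est = ivw_from_pairs(pairs)
        theta = (pairs["beta_out"] / pairs["beta_exp"]).to_numpy()
        sigma = np.abs(pairs["se_out"] / pairs["beta_exp"]).to_numpy()
        q, q_df, q_p = cochran_q(theta, sigma)
    # Steiger on the harmonized instruments actually used
    used = inst.records["snp_id"].isin(pairs["snp_id"]).to_numpy()
    from .instruments import InstrumentSet

    used_inst = InstrumentSet(
        protein_id=inst.protein_id,
        records=inst.records.loc[used].reset_index(drop=True),
        r2_explained=inst.r2_explained[used],
        f_stat=inst.f_stat[used],
    )
    out_records = outcome.df[outcome.df["snp_id"].isin(pairs["snp_id"])]
    steiger = steiger_test(used_inst, pqtl.meta, outcome.meta, out_records)
    return inst, used_inst, pairs, est, (q, q_df, q_p), steiger


def run_discovery(study: SyntheticStudy, cfg: PipelineConfig) -> pd.DataFrame:
    """Per-protein MR against the outcome with FDR and Steiger columns.

    The returned table is volcano-plot ready (log-OR, -log10 p, significance
    flag).  An empty table (no protein yields instruments) is not an error.
    """
    rows = []
    outcome_id = study.outcome.meta.trait_id
    for pid, pqtl in study.pqtl.items():
        res = _estimate_for_protein(
            pqtl, study.annotations[pid], study.ld[pid], study.outcome, cfg
        )
        if res is None:
            continue
        _, used_inst, pairs, est, (q, q_df, q_p), steiger = res
        or_, lo, hi = to_or(est)
        steiger_ok = steiger.correct_direction and steiger.steiger_pval < cfg.steiger_alpha
        rows.append(
            {
                "PROTEIN": pid,
                "OUTCOME": outcome_id,
                "METHOD": est.method,
                "NSNP": est.n_snps,
                "BETA": est.estimate,
                "SE": est.se,
                "OR": or_,
                "CI_LOW": lo,
                "CI_HIGH": hi,
                "P": est.pval,
                "FDR_Q": np.nan,
                "Q": q if q is not None else np.nan,
                "Q_DF": q_df if q_df is not None else 0,
                "Q_P": q_p if q_p is not None else np.nan,
                "F_MIN": float(np.min(used_inst.f_stat)),
                "R2_EXP": steiger.r2_exposure,
                "R2_OUT": steiger.r2_outcome,
                "STEIGER_P": steiger.steiger_pval,
                "STEIGER_PASS": steiger_ok,
                "NEG_LOG10_P": -np.log10(est.pval),
                "SIGNIFICANT": False,
            }
        )
    df = pd.DataFrame(rows, columns=DISCOVERY_COLUMNS)
    if len(df):
        df["FDR_Q"] = bh_fdr(df["P"].to_numpy(), m=cfg.fdr_family_m)
        df["SIGNIFICANT"] = df["FDR_Q"] < cfg.fdr_alpha
    return df


REPLICATION_COLUMNS = [
    "PROTEIN",
    "OUTCOME",
    "COMBO",
    "OR",
    "CI_LOW",
    "CI_HIGH",
    "P",
]


def _combo_estimate(pqtl, gene, ld, outcome, cfg):
    res = _estimate_for_protein(pqtl, gene, ld, outcome, cfg)
    if res is None:
        return None
    est = res[3]
    return est


def run_replication(
    study: SyntheticStudy, discovery: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replication estimates across dataset combinations plus meta-analysis.

    For each discovery-significant protein the three replication pairings
    (discovery pQTL x replication outcome, replication pQTL x discovery
    outcome, replication pQTL x replication outcome) are estimated with the
    same instrument-selection rules; the replication meta pools those three,
    and the overall meta pools them together with the discovery estimate,
    switching to random effects when I^2 exceeds the heterogeneity boundary.
    """
    if study.pqtl_replication is None or study.outcome_replication is None:
        raise ValueError("study carries no replication data; simulate or load it first")
    per_combo_rows = []
    meta_rows = []
    sig = discovery[discovery["SIGNIFICANT"]]
    for row in sig.itertuples(index=False):
        pid = row.PROTEIN
        gene = study.annotations[pid]
        ld = study.ld[pid]
        combos = [
            ("disc_pqtl~rep_outcome", study.pqtl[pid], study.outcome_replication),
            ("rep_pqtl~disc_outcome", study.pqtl_replication[pid], study.outcome),
            ("rep_pqtl~rep_outcome", study.pqtl_replication[pid], study.outcome_replication),
        ]
        rep_studies = []
        for label, pq, out in combos:
            est = _combo_estimate(pq, gene, ld, out, cfg)
            if est is None:
                continue
            or_, lo, hi = to_or(est)
            per_combo_rows.append(
                {
                    "PROTEIN": pid,
                    "OUTCOME": row.OUTCOME,
                    "COMBO": label,
                    "OR": or_,
                    "CI_LOW": lo,
                    "CI_HIGH": hi,
                    "P": est.pval,
                }
            )
            rep_studies.append(StudyEstimate(label=label, log_or=est.estimate, se=est.se))
        available = len(rep_studies) > 0
        rep_ok = False
        if available:
            rep_meta = meta_auto(rep_studies, i2_threshold=cfg.i2_threshold)
            all_meta = meta_auto(
                [StudyEstimate(label="discovery", log_or=row.BETA, se=row.SE)] + rep_studies,
                i2_threshold=cfg.i2_threshold,
            )
            rep_ok = replication_pass(rep_meta, row.BETA, alpha=cfg.replication_alpha)
        meta_rows.append(
            {
                "PROTEIN": pid,
                "OUTCOME": row.OUTCOME,
                "N_COMBOS": len(rep_studies),
                "REPLICATION_AVAILABLE": available,
                "REP_POOLED_OR": rep_meta.pooled_or if available else np.nan,
                "REP_CI_LOW": rep_meta.ci_low if available else np.nan,
                "REP_CI_HIGH": rep_meta.ci_high if available else np.nan,
                "REP_P": rep_meta.pval if available else np.nan,
                "REPLICATION_PASS": bool(rep_ok) if available else False,
                "I2": all_meta.i2 if available else np.nan,
                "MODEL": all_meta.model if available else "",
                "POOLED_OR": all_meta.pooled_or if available else np.nan,
                "POOLED_CI_LOW": all_meta.ci_low if available else np.nan,
                "POOLED_CI_HIGH": all_meta.ci_high if available else np.nan,
                "POOLED_P": all_meta.pval if available else np.nan,
            }
        )
    return pd.DataFrame(per_combo_rows, columns=REPLICATION_COLUMNS), pd.DataFrame(meta_rows)


def run_coloc(
    study: SyntheticStudy, proteins, cfg: PipelineConfig
) -> pd.DataFrame:
    """Colocalize each listed protein's cis region with the outcome."""
    rows = []
    for pid in proteins:
        pairs = kept_pairs(
            harmonize(study.pqtl[pid], study.outcome, eaf_window=cfg.eaf_window)
        )
        if len(pairs) == 0:
            log.info("%s: no shared region SNPs for colocalization", pid)
            continue
        region = ColocRegion(
            snp_ids=list(pairs["snp_id"]),
            beta1=pairs["beta_exp"].to_numpy(),
            se1=pairs["se_exp"].to_numpy(),
            beta2=pairs["beta_out"].to_numpy(),
            se2=pairs["se_out"].to_numpy(),
            trait1_type=study.pqtl[pid].meta.trait_type,
            trait2_type=study.outcome.meta.trait_type,
        )
        result = coloc_posteriors(
            region,
            priors=cfg.coloc_priors(),
            w1=cfg.coloc_w_continuous if region.trait1_type == "continuous" else cfg.coloc_w_binary,
            w2=cfg.coloc_w_binary if region.trait2_type == "binary" else cfg.coloc_w_continuous,
        )
        rows.append(
            {
                "PROTEIN": pid,
                "OUTCOME": study.outcome.meta.trait_id,
                "N_SNPS": result.n_snps,
                **{f"PP_{h}": result.pp[h] for h in ("H0", "H1", "H2", "H3", "H4")},
                "COLOC_PASS": coloc_pass(result, threshold=cfg.pph4_pass),
            }
        )
    return pd.DataFrame(rows)


def run_grading(
    discovery: pd.DataFrame,
    meta: pd.DataFrame,
    coloc_df: pd.DataFrame,
    cfg: PipelineConfig,
    external_flags: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Integrate the evidence streams and assign tiers.

    Graded rows are the discovery-significant proteins passing the Steiger
    direction filter (reverse-causal candidates are excluded before grading).
    Missing external flags default to False with a log note.
    """
    external_flags = external_flags or {}
    evidence = []
    meta_idx = meta.set_index("PROTEIN") if len(meta) else pd.DataFrame()
    coloc_idx = coloc_df.set_index("PROTEIN") if len(coloc_df) else pd.DataFrame()
    sig = discovery[discovery["SIGNIFICANT"]]
    for row in sig.itertuples(index=False):
        if not row.STEIGER_PASS:
            log.info("%s: failed direction filter; excluded from grading", row.PROTEIN)
            continue
        key = (row.PROTEIN, row.OUTCOME)
        flags = external_flags.get(key)
        if flags is None:
            log.info("%s/%s: no external flags; defaulting to False", *key)
            flags = {"cause_pass": False, "twas_pass": False, "ppi_drug_link": False}
        have_meta = len(meta_idx) > 0 and row.PROTEIN in meta_idx.index
        pph4 = (
            float(coloc_idx.loc[row.PROTEIN, "PP_H4"])
            if len(coloc_idx) and row.PROTEIN in coloc_idx.index
            else 0.0
        )
        evidence.append(
            EvidenceRecord(
                protein_id=row.PROTEIN,
                outcome_id=row.OUTCOME,
                discovery_pass=bool(row.FDR_Q < cfg.fdr_alpha),
                replication_available=bool(
                    have_meta and meta_idx.loc[row.PROTEIN, "REPLICATION_AVAILABLE"]
                ),
                replication_pass=bool(
                    have_meta and meta_idx.loc[row.PROTEIN, "REPLICATION_PASS"]
                ),
                cause_pass=flags["cause_pass"],
                pph4=pph4,
                coloc_pass=pph4 >= cfg.pph4_pass,
                twas_pass=flags["twas_pass"],
                steiger_pass=bool(row.STEIGER_PASS),
                ppi_drug_link=flags["ppi_drug_link"],
            )
        )
    return build_report(evidence, tier1_pph4=cfg.tier1_pph4, require_cause=cfg.require_cause)


def run_full(cfg: PipelineConfig, study: SyntheticStudy | None = None) -> dict:
    """Full pipeline over a study; returns the report bundle in memory.

    When ``study`` is None it is loaded from ``cfg.study_dir``.  Stages with
    missing inputs run as far as possible: absent replication data marks all
    candidates excluded, absent external flags default to False.
    """
    if study is None:
        if cfg.study_dir is None:
            raise ValueError("no study provided and cfg.study_dir is unset")
        if not Path(cfg.study_dir).exists():
            raise FileNotFoundError(f"study directory not found: {cfg.study_dir}")
        study = load_study(cfg.study_dir)
    discovery = run_discovery(study, cfg)
    sig = discovery[discovery["SIGNIFICANT"]]["PROTEIN"].tolist()
    if study.pqtl_replication is not None and study.outcome_replication is not None:
        combos, meta = run_replication(study, discovery, cfg)
    else:
        log.warning("no replication data: all graded candidates will be excluded")
        combos = pd.DataFrame(columns=REPLICATION_COLUMNS)
        meta = pd.DataFrame(columns=["PROTEIN", "REPLICATION_AVAILABLE", "REPLICATION_PASS"])
    coloc_df = run_coloc(study, sig, cfg)
    flags = None
    if cfg.evidence_flags is not None:
        flags = read_evidence_flags(cfg.evidence_flags)
    elif cfg.study_dir is not None and (Path(cfg.study_dir) / "evidence_flags.tsv").exists():
        flags = read_evidence_flags(Path(cfg.study_dir) / "evidence_flags.tsv")
    elif study.truth:
        from .simulate import planted_evidence_flags

        flags = planted_evidence_flags(study)
    graded, tier_counts = run_grading(discovery, meta, coloc_df, cfg, external_flags=flags)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": {
            "proteins_tested": int(len(discovery)),
            "significant": int(discovery["SIGNIFICANT"].sum()) if len(discovery) else 0,
            "graded": int(len(graded)),
            **tier_counts,
        },
    }
    return {
        "discovery": discovery,
        "replication_combos": combos,
        "meta": meta,
        "coloc": coloc_df,
        "graded": graded,
        "manifest": manifest,
    }


def write_report_bundle(bundle: dict, outdir: str | Path) -> None:
    """Persist the report bundle as TSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("discovery", "replication_combos", "meta", "coloc", "graded"):
        bundle[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    (outdir / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=1, sort_keys=True))
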