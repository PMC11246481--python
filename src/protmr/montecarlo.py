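"""Replicate-level calibration experiments on the synthetic generator.

These drivers repeat the single-protein analysis (simulate a cis region,
select instruments, harmonize, estimate) many times against known ground
truth, yielding the quantities the pipeline's statistical guarantees are
stated in: type-I error of the IVW test under a null causal effect,
bias of the recovered causal effect, Steiger direction accuracy, and the
colocalization posterior under shared versus distinct causal configurations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coloc import ColocPriors, ColocRegion, coloc_posteriors
from .direction import steiger_test
from .instruments import GeneAnnotation, InstrumentParams, LDMatrix, select_instruments
from .mr import ivw_from_pairs
from .simulate import (
    SimulationConfig,
    make_region_truth,
    simulate_ld,
    simulate_outcome,
    simulate_pqtl,
)
from .sumstats import SumStats, TraitMeta, harmonize, kept_pairs

__all__ = ["mr_replicates", "coloc_replicates", "steiger_replicates"]


def _region_setup(cfg: SimulationConfig):
    gene = GeneAnnotation(
        protein_id="P1",
        gene_symbol="G1",
        chrom="1",
        gene_start=5_000_000,
        gene_end=5_000_000 + 1000 * (cfg.snps_per_region - 1),
    )
    ld = simulate_ld(cfg.snps_per_region, cfg.ld_block_size, cfg.ld_rho)
    return gene, ld


def mr_replicates(
    cfg: SimulationConfig,
    n_reps: int,
    params: InstrumentParams = InstrumentParams(),
) -> pd.DataFrame:
    """Simulate/estimate loop: one IVW (or Wald) estimate per replicate.

    Returns one row per replicate with the causal estimate, its SE, p-value,
    the number of instruments, and the 95% CI coverage indicator against the
    true theta.  Replicates where no instrument survives selection carry NaN.
    """
    gene, ld = _region_setup(cfg)
    rng = np.random.default_rng(cfg.seed)
    from .mr import Z_975

    rows = []
    for _ in range(n_reps):
        truth = make_region_truth(
            cfg, rng, protein_id="P1", chrom="1", region_start=5_000_000, causal_protein=True
        )
        ld_rep = LDMatrix(snp_ids=list(truth.snp_ids), r2=ld.r2)
        pqtl = simulate_pqtl(cfg, truth, rng)
        outcome = simulate_outcome(cfg, truth, rng)
        inst = select_instruments(pqtl, gene, ld_rep, params)
        if inst.n_snps == 0:
            rows.append((np.nan, np.nan, np.nan, 0, np.nan))
            continue
        inst_ss = SumStats(meta=pqtl.meta, df=inst.records.copy())
        pairs = kept_pairs(harmonize(inst_ss, outcome))
        if len(pairs) == 0:
            rows.append((np.nan, np.nan, np.nan, 0, np.nan))
            continue
        est = ivw_from_pairs(pairs)
        est2 = ivw_from_pairs(pairs, second_order=True)
        # coverage is judged with the second-order delta SE: with the
        # outcome's effective n ~8x the exposure's, the exposure-noise term
        # is a material part of the ratio variance
        covered = abs(est2.estimate - truth.theta) <= Z_975 * est2.se
        rows.append((est.estimate, est.se, est.pval, est.n_snps, est2.se, covered))
    return pd.DataFrame(
        rows, columns=["theta_hat", "se", "pval", "n_snps", "se2", "covered"]
    )


def coloc_replicates(
    cfg: SimulationConfig,
    n_reps: int,
    priors: ColocPriors = ColocPriors(),
) -> pd.DataFrame:
    """Colocalization posteriors over replicates of one region.

    ``cfg.shared_causal`` decides whether the outcome's causal variants are
    the exposure's (H4 configurations) or disjoint (H3 configurations).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for _ in range(n_reps):
        truth = make_region_truth(
            cfg, rng, protein_id="P1", chrom="1", region_start=5_000_000, causal_protein=True
        )
        pqtl = simulate_pqtl(cfg, truth, rng)
        outcome = simulate_outcome(cfg, truth, rng)
        region = ColocRegion(
            snp_ids=list(truth.snp_ids),
            beta1=pqtl.df["beta"].to_numpy(),
            se1=pqtl.df["se"].to_numpy(),
            beta2=outcome.df["beta"].to_numpy(),
            se2=outcome.df["se"].to_numpy(),
            trait1_type="continuous",
            trait2_type="binary",
        )
        res = coloc_posteriors(region, priors=priors)
        rows.append((res.pp["H0"], res.pp["H1"], res.pp["H2"], res.pp["H3"], res.pp["H4"]))
    return pd.DataFrame(rows, columns=["pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4"])


def steiger_replicates(
    cfg: SimulationConfig,
    n_reps: int,
    params: InstrumentParams = InstrumentParams(),
) -> pd.DataFrame:
    """Direction-test verdicts over replicates: correct_direction and p."""
    gene, ld = _region_setup(cfg)
    rng = np.random.default_rng(cfg.seed)
    out_meta = TraitMeta(
        trait_id="outcome", trait_type="binary", n=cfg.n_outcome, n_cases=cfg.n_cases
    )
    rows = []
    for _ in range(n_reps):
        truth = make_region_truth(
            cfg, rng, protein_id="P1", chrom="1", region_start=5_000_000, causal_protein=True
        )
        ld_rep = LDMatrix(snp_ids=list(truth.snp_ids), r2=ld.r2)
        pqtl = simulate_pqtl(cfg, truth, rng)
        outcome = simulate_outcome(cfg, truth, rng, out_meta)
        inst = select_instruments(pqtl, gene, ld_rep, params)
        if inst.n_snps == 0:
            continue
        res = steiger_test(inst, pqtl.meta, out_meta, outcome.df)
        rows.append((res.correct_direction, res.steiger_pval))
    return pd.DataFrame(rows, columns=["correct_direction", "steiger_pval"])
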