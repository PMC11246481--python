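"""Synthetic-data generator: LD structure, calibration and determinism."""

import filecmp

import numpy as np
import pytest

from protmr.montecarlo import steiger_replicates
from protmr.simulate import (
    SimulationConfig,
    effective_sample_size,
    make_region_truth,
    simulate_ld,
    simulate_outcome,
    simulate_pqtl,
    simulate_replication,
    simulate_study,
    save_study,
    load_study,
)


class TestSimulateLD:
    def test_zero_rho_is_identity(self):
        ld = simulate_ld(10, 5, 0.0)
        assert np.array_equal(ld.r2, np.eye(10))

    def test_within_block_r2_is_rho_squared(self):
        ld = simulate_ld(10, 5, 0.9)
        block = ld.r2[:5, :5]
        off = block[~np.eye(5, dtype=bool)]
        assert off == pytest.approx(0.81)
        assert ld.r2[0, 5] == 0.0

    def test_correlation_is_positive_semidefinite(self):
        from protmr.simulate import _block_correlation

        for rho in (0.0, 0.5, 0.95):
            corr = _block_correlation(23, 5, rho)
            eigs = np.linalg.eigvalsh(corr)
            assert eigs.min() > -1e-10
            assert np.allclose(corr, corr.T)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, ld_rho=1.0)


class TestEffectiveSampleSize:
    def test_balanced_design_equals_n(self):
        assert effective_sample_size(1000, 500) == pytest.approx(1000)

    def test_imbalance_shrinks_effective_n(self):
        n_eff = effective_sample_size(275_911, 16_328)
        assert n_eff < 275_911
        assert n_eff == pytest.approx(
            4 / (1 / 16_328 + 1 / 259_583), rel=1e-12
        )

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(100, 100)


def _one_region(cfg, rng):
    return make_region_truth(
        cfg, rng, protein_id="P1", chrom="1", region_start=5_000_000, causal_protein=True
    )


class TestSimulatePqtl:
    def test_null_regions_rarely_reach_genome_wide_significance(self):
        cfg = SimulationConfig(
            seed=21, snps_per_region=100, ld_block_size=10, pqtl_effect_b=0.0
        )
        rng = np.random.default_rng(cfg.seed)
        hits = 0
        for _ in range(100):  # 10^4 SNPs total under the null
            truth = _one_region(cfg, rng)
            truth.b_joint[:] = 0.0
            ss = simulate_pqtl(cfg, truth, rng)
            hits += int((ss.df["pval"] < 5e-8).sum())
        assert hits <= 2

    def test_planted_z10_signal_detected(self):
        cfg = SimulationConfig(
            seed=22, snps_per_region=20, ld_block_size=5, target_pqtl_z=10, n_causal_snps=1
        )
        rng = np.random.default_rng(cfg.seed)
        detected = 0
        n_reps = 500
        for _ in range(n_reps):
            truth = _one_region(cfg, rng)
            ss = simulate_pqtl(cfg, truth, rng)
            causal = truth.causal_idx_exposure[0]
            detected += int(ss.df["pval"].iloc[causal] < 5e-8)
        assert detected / n_reps >= 0.99

    def test_mean_observed_beta_unbiased_at_causal_snp(self):
        cfg = SimulationConfig(
            seed=23, snps_per_region=20, ld_block_size=5, n_causal_snps=1
        )
        rng = np.random.default_rng(cfg.seed)
        truth = _one_region(cfg, rng)
        causal = truth.causal_idx_exposure[0]
        betas = np.array(
            [simulate_pqtl(cfg, truth, rng).df["beta"].iloc[causal] for _ in range(1000)]
        )
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        # the marginal mean at an isolated causal SNP is the joint effect
        assert abs(betas.mean() - truth.b_joint[causal]) <= 3 * mc_se


class TestSimulateOutcome:
    def test_shared_causal_outcome_effect_scales_with_theta(self):
        cfg = SimulationConfig(
            seed=24, snps_per_region=20, ld_block_size=5, n_causal_snps=1,
            causal_effect_theta=0.3, target_pqtl_z=10,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = _one_region(cfg, rng)
        causal = truth.causal_idx_exposure[0]
        assert truth.g_joint[causal] == pytest.approx(0.3 * truth.b_joint[causal])
        betas = np.array(
            [
                simulate_outcome(cfg, truth, rng).df["beta"].iloc[causal]
                for _ in range(500)
            ]
        )
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - truth.g_joint[causal]) <= 3.5 * mc_se

    def test_distinct_causal_sets_are_disjoint(self):
        cfg = SimulationConfig(
            seed=25, snps_per_region=50, ld_block_size=10, shared_causal=False
        )
        rng = np.random.default_rng(cfg.seed)
        truth = _one_region(cfg, rng)
        assert len(truth.causal_idx_outcome) > 0
        assert not set(truth.causal_idx_exposure) & set(truth.causal_idx_outcome)
        # distinct causal variants sit in different LD blocks entirely
        blocks_exp = set(truth.causal_idx_exposure // cfg.ld_block_size)
        blocks_out = set(truth.causal_idx_outcome // cfg.ld_block_size)
        assert not blocks_exp & blocks_out


class TestSteigerCalibration:
    def test_direction_correct_in_nearly_all_replicates(self):
        cfg = SimulationConfig(
            seed=26, snps_per_region=30, ld_block_size=5, target_pqtl_z=8,
            causal_effect_theta=0.3, n_causal_snps=2,
        )
        df = steiger_replicates(cfg, 200)
        assert len(df) >= 190
        assert df["correct_direction"].mean() >= 0.99


class TestStudyPersistence:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=31, n_proteins=3, n_causal_proteins=1, snps_per_region=20)
        a, b = tmp_path / "a", tmp_path / "b"
        for d in (a, b):
            save_study(simulate_replication(simulate_study(cfg)), d)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel

    def test_roundtrip_preserves_study(self, tmp_path):
        cfg = SimulationConfig(seed=32, n_proteins=2, n_causal_proteins=1, snps_per_region=10)
        study = simulate_replication(simulate_study(cfg))
        save_study(study, tmp_path)
        back = load_study(tmp_path)
        assert set(back.pqtl) == set(study.pqtl)
        assert back.cfg == study.cfg
        pid = next(iter(study.pqtl))
        assert back.pqtl[pid].df["beta"].tolist() == pytest.approx(
            study.pqtl[pid].df["beta"].tolist()
        )
        assert np.array_equal(
            back.truth[pid].causal_idx_exposure, study.truth[pid].causal_idx_exposure
        )
        assert back.outcome_replication is not None

    def test_different_seeds_differ(self):
        s1 = simulate_study(SimulationConfig(seed=1, n_proteins=1, snps_per_region=10))
        s2 = simulate_study(SimulationConfig(seed=2, n_proteins=1, snps_per_region=10))
        pid = next(iter(s1.pqtl))
        assert s1.pqtl[pid].df["beta"].tolist() != s2.pqtl[pid].df["beta"].tolist()
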