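#!/usr/bin/env python
"""Simulate the synthetic study cohorts.

Generates the discovery proteomics panel (7213 samples), an independent
replication panel (35,559 samples), and FinnGen-shaped binary outcome GWAS
(275,911 samples, 16,328 cases) for 55 proteins -- 5 with a planted causal
effect (theta = 0.3 log-odds per SD) and 50 null -- each as a 100-SNP cis
region with block-exchangeable LD.  Writes the study directory consumed by
the downstream steps.
"""

import argparse
from pathlib import Path

from protmr.simulate import SimulationConfig, save_study, simulate_replication, simulate_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2026)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, target_pqtl_z=9, n_causal_snps=1)
    study = simulate_replication(simulate_study(cfg))
    outdir = RESULTS / "study"
    save_study(study, outdir)
    print(f"wrote {cfg.n_proteins} protein regions ({cfg.snps_per_region} SNPs each) to {outdir}")
    print(f"planted causal proteins: {', '.join(study.causal_proteins)}")


if __name__ == "__main__":
    main()
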