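#!/usr/bin/env python
"""Replication across dataset combinations and meta-analysis.

Each discovery-significant protein is re-estimated in the three replication
pairings (discovery pQTL x replication outcome, replication pQTL x discovery
outcome, replication pQTL x replication outcome).  The replication pairings
are pooled to decide replication pass/fail; all four estimates are pooled for
the overall meta, switching to DerSimonian-Laird random effects when I^2
exceeds 50%.
"""

from pathlib import Path

import pandas as pd

from protmr.pipeline import PipelineConfig, run_replication
from protmr.simulate import load_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = load_study(RESULTS / "study")
    cfg = PipelineConfig(study_dir=str(RESULTS / "study"))
    discovery = pd.read_csv(RESULTS / "discovery.tsv", sep="\t")
    combos, meta = run_replication(study, discovery, cfg)
    combos.to_csv(RESULTS / "replication_combos.tsv", sep="\t", index=False, float_format="%.6g")
    meta.to_csv(RESULTS / "replication_meta.tsv", sep="\t", index=False, float_format="%.6g")

    n_pass = int(meta["REPLICATION_PASS"].sum())
    print(f"replicated {len(meta)} candidates; {n_pass} passed (pooled p < {cfg.replication_alpha}, concordant sign)")
    print(meta[["PROTEIN", "REPLICATION_PASS", "I2", "MODEL", "POOLED_OR", "POOLED_P"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
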