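#!/usr/bin/env python
"""Evidence integration and drug-target tiering.

Combines discovery significance, replication, the external pleiotropy-check /
TWAS / drug-target-link flags, colocalization PPH4 and the Steiger verdict
into the four-tier evidence grade (plus Excluded for candidates without
replication data).
"""

import json
from pathlib import Path

import pandas as pd

from protmr.grading import read_evidence_flags
from protmr.pipeline import PipelineConfig, run_grading

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig(study_dir=str(RESULTS / "study"))
    discovery = pd.read_csv(RESULTS / "discovery.tsv", sep="\t")
    meta = pd.read_csv(RESULTS / "replication_meta.tsv", sep="\t")
    coloc = pd.read_csv(RESULTS / "coloc.tsv", sep="\t")
    flags = read_evidence_flags(RESULTS / "study" / "evidence_flags.tsv")
    graded, counts = run_grading(discovery, meta, coloc, cfg, external_flags=flags)
    graded.to_csv(RESULTS / "graded.tsv", sep="\t", index=False, float_format="%.6g")
    (RESULTS / "tier_counts.json").write_text(json.dumps(counts, indent=1, sort_keys=True))

    print("tier counts:", {k: v for k, v in counts.items() if v})
    print(graded[["PROTEIN", "OUTCOME", "REPLICATION_PASS", "PPH4", "TWAS_PASS", "TIER"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
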