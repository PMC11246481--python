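"""Evidence integration and tiered grading of candidate drug targets.

Each protein-outcome pair accumulates a vector of evidence flags: discovery
FDR significance, replication availability and pass, a genome-wide Bayesian
pleiotropy check (CAUSE, consumed as an external flag), the colocalization
posterior PPH4, tissue-level TWAS validation (external flag), the Steiger
direction verdict, and whether the protein links to a known drug target in
the PPI network (external flag).  Tiers:

* Excluded -- no replication data (instrument absent from the replication
  pQTL panel).
* Tier 4 (downgrade) -- the pleiotropy check failed; the association is
  treated as potentially driven by incoherent pleiotropy regardless of other
  evidence.
* Tier 1 -- PPH4 above the colocalization bar AND replication pass AND TWAS
  pass.
* Tier 2 -- linked to a known drug target AND validated by at least one of
  replication or TWAS.
* Tier 3 -- any single line of support: PPH4 above the bar, replication,
  TWAS, or a drug-target link.
* Tier 4 -- none of the above.

The Tier-1/Tier-3 colocalization criterion is strict (PPH4 > 0.8) while the
stand-alone colocalization pass rule is inclusive (PPH4 >= 0.8); both
thresholds are separate configuration values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "EvidenceRecord",
    "TierAssignment",
    "grade_target",
    "build_report",
    "read_evidence_flags",
]

TIER_ORDER = {"1": 0, "2": 1, "3": 2, "4": 3, "excluded": 4}


@dataclass(frozen=True)
class EvidenceRecord:
    """All evidence flags for one protein-outcome pair."""

    protein_id: str
    outcome_id: str
    discovery_pass: bool = False
    replication_available: bool = False
    replication_pass: bool = False
    cause_pass: bool = False
    pph4: float = 0.0
    coloc_pass: bool = False
    twas_pass: bool = False
    steiger_pass: bool = False
    ppi_drug_link: bool = False


@dataclass(frozen=True)
class TierAssignment:
    tier: str  # "1" | "2" | "3" | "4" | "excluded"
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tier not in TIER_ORDER:
            raise ValueError(f"unknown tier {self.tier!r}")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")


def grade_target(
    e: EvidenceRecord,
    tier1_pph4: float = 0.8,
    require_cause: bool = True,
) -> TierAssignment:
    """Assign the evidence tier for one protein-outcome pair.

    ``tier1_pph4`` is the strict colocalization bar used inside the tier
    rules; ``require_cause`` applies the pleiotropy-check downgrade (a failed
    check sends the pair to Tier 4 outright).
    """
    if not e.replication_available:
        return TierAssignment("excluded", ("no replication data for this protein",))
    if require_cause and not e.cause_pass:
        return TierAssignment(
            "4", ("pleiotropy check failed: downgraded to Tier 4",)
        )
    coloc_hit = e.pph4 > tier1_pph4
    if coloc_hit and e.replication_pass and e.twas_pass:
        return TierAssignment(
            "1", ("PPH4 above bar", "replication pass", "TWAS pass")
        )
    if e.ppi_drug_link and (e.replication_pass or e.twas_pass):
        hits = ["drug-target PPI link"]
        if e.replication_pass:
            hits.append("replication pass")
        if e.twas_pass:
            hits.append("TWAS pass")
        return TierAssignment("2", tuple(hits))
    hits = []
    if coloc_hit:
        hits.append("PPH4 above bar")
    if e.replication_pass:
        hits.append("replication pass")
    if e.twas_pass:
        hits.append("TWAS pass")
    if e.ppi_drug_link:
        hits.append("drug-target PPI link")
    if hits:
        return TierAssignment("3", tuple(hits))
    return TierAssignment("4", ("no supporting evidence line",))


REPORT_COLUMNS = [
    "PROTEIN",
    "OUTCOME",
    "DISCOVERY_PASS",
    "REPLICATION_AVAILABLE",
    "REPLICATION_PASS",
    "CAUSE_PASS",
    "PPH4",
    "COLOC_PASS",
    "TWAS_PASS",
    "STEIGER_PASS",
    "PPI_DRUG_LINK",
    "TIER",
    "RATIONALE",
]


def build_report(
    evidence: list[EvidenceRecord],
    tier1_pph4: float = 0.8,
    require_cause: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Grade every pair; return the flag table plus per-tier counts."""
    rows = []
    counts: Counter = Counter({t: 0 for t in TIER_ORDER})
    for e in evidence:
        tier = grade_target(e, tier1_pph4=tier1_pph4, require_cause=require_cause)
        counts[tier.tier] += 1
        rows.append(
            (
                e.protein_id,
                e.outcome_id,
                e.discovery_pass,
                e.replication_available,
                e.replication_pass,
                e.cause_pass,
                e.pph4,
                e.coloc_pass,
                e.twas_pass,
                e.steiger_pass,
                e.ppi_drug_link,
                tier.tier,
                "; ".join(tier.rationale),
            )
        )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    summary = {f"tier_{t}" if t != "excluded" else "excluded": counts[t] for t in TIER_ORDER}
    summary["total"] = len(evidence)
    return table, summary


def read_evidence_flags(path: str | Path) -> dict[tuple[str, str], dict]:
    """External validation flags from TSV {PROTEIN, OUTCOME, CAUSE_PASS,
    TWAS_PASS, PPI_DRUG_LINK} so externally computed results plug in."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples(index=False):
        out[(str(r.PROTEIN), str(r.OUTCOME))] = {
            "cause_pass": bool(r.CAUSE_PASS),
            "twas_pass": bool(r.TWAS_PASS),
            "ppi_drug_link": bool(r.PPI_DRUG_LINK),
        }
    return out
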