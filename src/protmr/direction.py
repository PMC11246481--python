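"""Steiger directionality filtering.

A valid protein instrument should explain more variance in the protein than
in the disease outcome; the reverse pattern suggests the causal arrow points
the other way.  Per trait, the instrument set's variance explained is the sum
of per-SNP pseudo-R^2 values (instruments are clumped, so the sum is an
adequate approximation), and the two |r| values are compared with a two-sample
z-test on the Fisher transform:

    z = (atanh(r_exp) - atanh(r_out)) / sqrt(1/(n_exp-3) + 1/(n_out-3))

reported two-sided.  The direction verdict (r2_exp > r2_out) is kept separate
from the significance of the comparison; proteins whose instruments fail the
direction test are excluded from graded output as reverse-causal.

For binary outcomes the same observed-scale pseudo-R^2 is used as for the
protein; this is a documented approximation, adequate for the Pass/Fail use
the filter is put to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet, variance_explained
from .sumstats import TraitMeta

__all__ = ["SteigerResult", "steiger_from_r2", "steiger_test"]


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    steiger_pval: float


def steiger_from_r2(r2_exp: float, n_exp: int, r2_out: float, n_out: int) -> SteigerResult:
    """Directionality test from total variance explained in each trait."""
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("Steiger test requires n > 3 for both traits")
    for r2 in (r2_exp, r2_out):
        if not 0 <= r2 < 1:
            raise ValueError("r2 values must lie in [0, 1)")
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / denom
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        correct_direction=r2_exp > r2_out,
        steiger_pval=float(2.0 * stats.norm.sf(abs(z))),
    )


def steiger_test(
    instruments: InstrumentSet,
    exposure_meta: TraitMeta,
    outcome_meta: TraitMeta,
    outcome_records: pd.DataFrame,
) -> SteigerResult:
    """Steiger test for one protein's instrument set against the outcome.

    ``outcome_records`` must contain the instrument SNPs with outcome-scale
    ``beta`` and ``se`` columns keyed by ``snp_id``.
    """
    r2_exp = min(float(np.sum(instruments.r2_explained)), 1.0 - 1e-12)
    out = outcome_records.set_index("snp_id")
    r2_out = 0.0
    for snp in instruments.records["snp_id"]:
        if snp not in out.index:
            raise KeyError(f"instrument {snp} absent from outcome records")
        row = out.loc[snp]
        r2_out += variance_explained(float(row["beta"]), float(row["se"]), outcome_meta.n)
    r2_out = min(r2_out, 1.0 - 1e-12)
    return steiger_from_r2(r2_exp, exposure_meta.n, r2_out, outcome_meta.n)
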