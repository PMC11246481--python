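"""Worked-example fixtures and the harness binding them to operations.

Each fixture is a transcribed cell (or set of cells) from the published
worked examples this pipeline reproduces: an input tuple, the expected
value, a tolerance justified by the print precision (4 significant digits
for OR/CI-derived quantities, half a percentage point for I^2), and a
provenance string naming the row it came from.  The harness dispatches on
the operation name and computes through the public API only; fixtures
without provenance or tolerance are refused.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .grading import EvidenceRecord, grade_target
from .instruments import f_statistic
from .meta import StudyEstimate, i_squared, meta_fixed, meta_random, select_model
from .mr import p_from_or_ci
from scipy import stats as _stats

__all__ = ["PaperFixture", "FixtureOutcome", "load_fixtures", "run_fixture"]


class FixtureError(ValueError):
    """A fixture is malformed or references an unknown operation."""


@dataclass(frozen=True)
class PaperFixture:
    fixture_id: str
    operation: str
    inputs: dict
    expected: float | str
    tolerance: float
    source: str
    mode: str = "rel"  # "rel" fraction | "abs" difference | "exact" equality

    def __post_init__(self) -> None:
        if not self.source:
            raise FixtureError(f"{self.fixture_id}: fixture lacks provenance")
        if self.mode not in ("rel", "abs", "exact"):
            raise FixtureError(f"{self.fixture_id}: unknown comparison mode {self.mode!r}")
        if self.mode != "exact" and not self.tolerance > 0:
            raise FixtureError(f"{self.fixture_id}: fixture lacks a positive tolerance")


@dataclass(frozen=True)
class FixtureOutcome:
    fixture_id: str
    computed: float | str
    expected: float | str
    passed: bool


def _studies(inputs: dict) -> list[StudyEstimate]:
    return [
        StudyEstimate.from_or_ci(f"s{i}", *triple)
        for i, triple in enumerate(inputs["studies"])
    ]


def _dispatch(f: PaperFixture):
    op = f.operation
    if op == "p_from_or_ci":
        return p_from_or_ci(f.inputs["or"], f.inputs["ci_low"], f.inputs["ci_high"])
    if op == "chi2_upper_p":
        return float(_stats.chi2.sf(f.inputs["q"], f.inputs["df"]))
    if op == "meta_fixed_pooled_or":
        return meta_fixed(_studies(f.inputs)).pooled_or
    if op == "meta_fixed_pooled_log_or":
        return meta_fixed(_studies(f.inputs)).pooled_log_or
    if op == "meta_random_pooled_or":
        return meta_random(_studies(f.inputs)).pooled_or
    if op == "i_squared_pct":
        m = meta_fixed(_studies(f.inputs))
        return 100.0 * i_squared(m.q, m.df)
    if op == "select_model":
        return select_model(f.inputs["i2"])
    if op == "f_statistic":
        return f_statistic(f.inputs["r2"], f.inputs["n"], f.inputs.get("k", 1))
    if op == "grade_target":
        return grade_target(EvidenceRecord(**f.inputs["evidence"])).tier
    raise FixtureError(f"{f.fixture_id}: unknown operation {op!r}")


def run_fixture(f: PaperFixture) -> FixtureOutcome:
    """Compute the fixture's operation and compare within its tolerance."""
    computed = _dispatch(f)
    if f.mode == "exact":
        passed = computed == f.expected
    elif f.mode == "abs":
        passed = abs(float(computed) - float(f.expected)) <= f.tolerance
    else:
        expected = float(f.expected)
        passed = math.isclose(float(computed), expected, rel_tol=f.tolerance)
    return FixtureOutcome(
        fixture_id=f.fixture_id, computed=computed, expected=f.expected, passed=passed
    )


def load_fixtures() -> list[PaperFixture]:
    """All bundled worked-example fixtures."""
    raw = json.loads(
        resources.files("protmr.data").joinpath("worked_examples.json").read_text()
    )
    return [PaperFixture(**entry) for entry in raw]
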