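"""Meta-analysis of MR estimates across dataset combinations.

The discovery estimate and the replication estimates (different pQTL panel /
outcome GWAS pairings) are pooled on the log-OR scale.  Fixed-effect pooling
is inverse-variance weighting; when between-study heterogeneity is material
-- I^2 = max(0, (Q - df)/Q) strictly above 50% -- a DerSimonian-Laird
random-effects model is used instead, with

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)),  w = 1/se^2,

and weights 1/(se_i^2 + tau^2).  A replication passes when the pooled p is
below 0.05 and the pooled sign agrees with the discovery sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mr import Z_975, se_from_ci

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "meta_fixed",
    "meta_random",
    "meta_auto",
    "i_squared",
    "select_model",
    "replication_pass",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One dataset-combination estimate on the log-OR scale."""

    label: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.label}: se must be positive")

    @classmethod
    def from_or_ci(cls, label: str, or_: float, ci_low: float, ci_high: float) -> "StudyEstimate":
        """Build from a printed OR and 95% CI (SE recovered from the CI)."""
        return cls(label=label, log_or=math.log(or_), se=se_from_ci(ci_low, ci_high))


@dataclass
class MetaResult:
    pooled_log_or: float
    pooled_se: float
    pooled_or: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    i2: float
    tau2: float
    model: str  # "fixed" or "random"
    pval: float
    n_studies: int


def i_squared(q: float, df: int) -> float:
    """Heterogeneity fraction max(0, (Q - df)/Q); invariant to SE rescaling."""
    if df < 1:
        raise ValueError("i_squared requires df >= 1")
    if q < 0:
        raise ValueError("Q must be nonnegative")
    if q == 0:
        return 0.0
    return max(0.0, (q - df) / q)


def select_model(i2: float) -> str:
    """Random effects iff I^2 strictly above 50%; ties go to fixed."""
    if not 0 <= i2 < 1:
        raise ValueError("i2 must be in [0, 1)")
    return "random" if i2 > 0.5 else "fixed"


def _q_stats(log_ors: np.ndarray, ses: np.ndarray) -> tuple[float, int, float, np.ndarray]:
    w = 1.0 / ses**2
    pooled = float(np.sum(w * log_ors) / np.sum(w))
    q = float(np.sum(w * (log_ors - pooled) ** 2))
    df = max(len(log_ors) - 1, 1) if len(log_ors) > 1 else 0
    return q, df, pooled, w


def _finish(pooled: float, se: float, q: float, df: int, i2: float, tau2: float,
            model: str, k: int) -> MetaResult:
    z = pooled / se
    return MetaResult(
        pooled_log_or=pooled,
        pooled_se=se,
        pooled_or=math.exp(pooled),
        ci_low=math.exp(pooled - Z_975 * se),
        ci_high=math.exp(pooled + Z_975 * se),
        q=q,
        df=df,
        i2=i2,
        tau2=tau2,
        model=model,
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_studies=k,
    )


def _arrays(studies) -> tuple[np.ndarray, np.ndarray]:
    if len(studies) == 0:
        raise ValueError("meta-analysis needs at least one study")
    return (
        np.array([s.log_or for s in studies], dtype=float),
        np.array([s.se for s in studies], dtype=float),
    )


def meta_fixed(studies) -> MetaResult:
    """Fixed-effect (inverse-variance) pooling on the log-OR scale."""
    log_ors, ses = _arrays(studies)
    q, df, pooled, w = _q_stats(log_ors, ses)
    se = float(1.0 / math.sqrt(np.sum(w)))
    i2 = i_squared(q, df) if df >= 1 else 0.0
    return _finish(pooled, se, q, df, i2, 0.0, "fixed", len(studies))


def meta_random(studies) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    With a single study there is nothing to estimate heterogeneity from and
    the result falls back to the fixed-effect answer.
    """
    log_ors, ses = _arrays(studies)
    if len(studies) < 2:
        return meta_fixed(studies)
    q, df, _, w = _q_stats(log_ors, ses)
    sw = float(np.sum(w))
    denom = sw - float(np.sum(w**2)) / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w_star * log_ors) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    i2 = i_squared(q, df)
    return _finish(pooled, se, q, df, i2, tau2, "random", len(studies))


def meta_auto(studies, i2_threshold: float = 0.5) -> MetaResult:
    """Pool with the model the heterogeneity rule selects.

    Fixed-effect Q/I^2 are computed first; the random-effects model is adopted
    iff I^2 strictly exceeds ``i2_threshold``.
    """
    fixed = meta_fixed(studies)
    if len(studies) >= 2 and fixed.i2 > i2_threshold:
        return meta_random(studies)
    return fixed


def replication_pass(meta: MetaResult, discovery_sign: float, alpha: float = 0.05) -> bool:
    """Replication passes when pooled p < alpha and the sign is concordant."""
    if discovery_sign == 0:
        return False
    return meta.pval < alpha and math.copysign(1.0, meta.pooled_log_or) == math.copysign(
        1.0, discovery_sign
    )
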