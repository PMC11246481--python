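"""Two-sample MR estimators and reporting utilities.

A protein instrumented by a single SNP gets the Wald ratio
``theta = beta_out / beta_exp`` with first-order delta SE ``|se_out/beta_exp|``
(a second-order option adds the exposure-noise term).  With two or more
instruments, per-SNP ratios are pooled by fixed-effect inverse-variance
weighting; between-instrument heterogeneity is Cochran's Q against a
chi-square with k-1 df.  Effects are log odds per SD of genetically predicted
protein level and are reported as OR with a normal-theory CI; the
Benjamini-Hochberg step-up controls the FDR across the per-outcome family of
proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "MRResult",
    "wald_ratio",
    "ivw",
    "ivw_from_pairs",
    "cochran_q",
    "to_or",
    "p_from_or_ci",
    "se_from_ci",
    "bh_fdr",
]

# exact standard-normal 97.5% quantile to the precision used throughout;
# fixed (rather than 1.96) so results are deterministic to full precision
Z_975 = 1.959964


def _p_from_z(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class MREstimate:
    """Causal log-odds per SD estimate with its normal-theory inference."""

    estimate: float
    se: float
    zscore: float
    pval: float
    n_snps: int
    method: str  # "wald" or "ivw"

    @classmethod
    def from_beta_se(cls, beta: float, se: float, n_snps: int, method: str) -> "MREstimate":
        if se <= 0:
            raise ValueError("se must be positive")
        z = beta / se
        return cls(estimate=beta, se=se, zscore=z, pval=_p_from_z(z), n_snps=n_snps, method=method)


@dataclass
class MRResult:
    """One protein-outcome MR row: estimate, OR scale, FDR and heterogeneity."""

    protein_id: str
    outcome_id: str
    est: MREstimate
    or_: float
    ci_low: float
    ci_high: float
    fdr_q: float = float("nan")
    q_stat: float = float("nan")
    q_df: int = 0
    q_pval: float = float("nan")


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, second_order: bool = False
) -> MREstimate:
    """Single-instrument causal estimate by/bx.

    First-order delta SE is |sy/bx|; the second-order option adds the
    contribution of exposure-beta noise, se^2 = sy^2/bx^2 + by^2 sx^2 / bx^4.
    """
    if bx == 0:
        raise ZeroDivisionError("degenerate instrument: exposure beta is zero")
    est = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = abs(sy / bx)
    return MREstimate.from_beta_se(est, se, n_snps=1, method="wald")


def _ratio_arrays(bx, sx, by, sy, second_order: bool = False):
    bx = np.asarray(bx, dtype=float)
    sx = np.asarray(sx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    ok = bx != 0
    if not ok.any():
        raise ZeroDivisionError("all instruments degenerate (exposure beta zero)")
    theta = by[ok] / bx[ok]
    if second_order:
        sigma = np.sqrt(sy[ok] ** 2 / bx[ok] ** 2 + by[ok] ** 2 * sx[ok] ** 2 / bx[ok] ** 4)
    else:
        sigma = np.abs(sy[ok] / bx[ok])
    return theta, sigma


def ivw(bx, sx, by, sy, second_order: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted pooling of per-SNP Wald ratios.

    With one usable instrument this reduces exactly to :func:`wald_ratio`.
    With first-order weights it equals the zero-intercept WLS regression of
    by on bx with weights 1/sy^2; the second-order option widens each ratio's
    SE by the exposure-beta noise term (relevant when the outcome's effective
    sample size is much larger than the exposure's).
    """
    theta, sigma = _ratio_arrays(bx, sx, by, sy, second_order=second_order)
    if theta.size == 1:  # exact Wald reduction, no round trip through weights
        return MREstimate.from_beta_se(float(theta[0]), float(sigma[0]), 1, "wald")
    w = 1.0 / sigma**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    method = "wald" if theta.size == 1 else "ivw"
    return MREstimate.from_beta_se(pooled, se, n_snps=int(theta.size), method=method)


def ivw_from_pairs(pairs: pd.DataFrame, second_order: bool = False) -> MREstimate:
    """IVW over the kept rows of a harmonization result."""
    return ivw(
        pairs["beta_exp"].to_numpy(),
        pairs["se_exp"].to_numpy(),
        pairs["beta_out"].to_numpy(),
        pairs["se_out"].to_numpy(),
        second_order=second_order,
    )


def cochran_q(theta_i, sigma_i) -> tuple[float, int, float]:
    """Cochran's Q over per-instrument ratios: Q, df = k-1, upper-tail p."""
    theta = np.asarray(theta_i, dtype=float)
    sigma = np.asarray(sigma_i, dtype=float)
    if theta.size < 2:
        raise ValueError("Cochran's Q needs at least two estimates")
    w = 1.0 / sigma**2
    pooled = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = int(theta.size - 1)
    return q, df, float(stats.chi2.sf(q, df))


def to_or(est: MREstimate, conf: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into OR with a normal-theory CI."""
    z = float(stats.norm.ppf(0.5 + conf / 2)) if conf != 0.95 else Z_975
    return (
        math.exp(est.estimate),
        math.exp(est.estimate - z * est.se),
        math.exp(est.estimate + z * est.se),
    )


def se_from_ci(ci_low: float, ci_high: float, conf: float = 0.95) -> float:
    """Recover the log-scale SE from a printed OR confidence interval."""
    if not 0 < ci_low < ci_high:
        raise ValueError("need 0 < ci_low < ci_high")
    z = float(stats.norm.ppf(0.5 + conf / 2)) if conf != 0.95 else Z_975
    return (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def p_from_or_ci(or_: float, ci_low: float, ci_high: float, conf: float = 0.95) -> float:
    """Two-sided p implied by an OR and its CI (consistency relation)."""
    if not 0 < ci_low <= or_ <= ci_high:
        raise ValueError("need ci_low <= or_ <= ci_high, all positive")
    se = se_from_ci(ci_low, ci_high, conf)
    if se == 0:
        return 1.0 if math.log(or_) == 0 else 0.0
    return _p_from_z(math.log(or_) / se)


def bh_fdr(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    ``m`` overrides the family size (defaults to len(pvals)) for the case
    where the vector is a significant subset of a larger testing family.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    m_eff = int(m) if m is not None else p.size
    if m_eff < p.size:
        raise ValueError("family size m cannot be smaller than the vector")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m_eff / (np.arange(p.size) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
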