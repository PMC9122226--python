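"""Cross-cohort meta-analysis and the pre-registered replication verdict.

Per-cohort MR estimates are combined by fixed-effects inverse-variance
weighting, with Cochran's Q across cohorts.  Estimates from two cohorts (or
two instruments) are compared with a z-test on the difference,
``z = (b_a - b_b)/sqrt(se_a^2 + se_b^2)``; a Welch-style t reference with a
caller-supplied df is available but off by default, since no df is
derivable from summary statistics alone.

The replication verdict applies four pre-registered criteria to a
candidate effect with a known prior sign:

* 1a — the largest single cohort's MR beta has the prior sign;
* 1b — that analysis's p-value is below ``p1_threshold`` (default 1.1e-5);
* 2a — the meta-analysis of the remaining cohorts has the prior sign;
* 2b — that meta-analysis p-value is below ``p2_threshold`` (default
  0.025, i.e. 0.05 Bonferroni-corrected for two traits).

All comparisons are strict inequalities; a result exactly at a threshold
fails it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import (
    HeterogeneityResult,
    InsufficientInstrumentsError,
    MREstimate,
    cochran_q,
)
from .summary_stats import ValidationError

__all__ = [
    "CohortResult",
    "ReplicationVerdict",
    "meta_fixed",
    "beta_comparison_test",
    "evaluate_replication",
]


@dataclass(frozen=True)
class CohortResult:
    """One cohort's MR estimate for one exposure-outcome pair."""

    cohort: str
    estimate: MREstimate
    n_outcome: float


@dataclass(frozen=True)
class ReplicationVerdict:
    """Outcome of the four replication criteria, with observed quantities."""

    criterion_1a: bool
    criterion_1b: bool
    criterion_2a: bool
    criterion_2b: bool
    observed: dict
    thresholds: dict

    @property
    def overall(self) -> bool:
        return (
            self.criterion_1a
            and self.criterion_1b
            and self.criterion_2a
            and self.criterion_2b
        )


def meta_fixed(
    results: list[CohortResult],
) -> tuple[MREstimate, HeterogeneityResult]:
    """Fixed-effects IVW meta-analysis of per-cohort estimates.

    Returns the pooled estimate (normal-theory p-value) and Cochran's Q
    across cohorts (df = k-1).
    """
    if len(results) < 2:
        raise InsufficientInstrumentsError(
            f"meta-analysis requires >= 2 cohorts, got {len(results)}"
        )
    b = np.array([r.estimate.beta for r in results], dtype=float)
    s = np.array([r.estimate.se for r in results], dtype=float)
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    n_iv = max(r.estimate.n_iv for r in results)
    est = MREstimate(
        "ivw_fe", beta, se, p, n_iv,
        extras={"cohorts": [r.cohort for r in results]},
    )
    het = cochran_q([(r.estimate.beta, r.estimate.se) for r in results])
    return est, het


def beta_comparison_test(
    a: tuple[float, float],
    b: tuple[float, float],
    df: float | None = None,
) -> float:
    """Two-sided p-value for the difference between two (beta, se) estimates.

    Normal reference by default; pass ``df`` for a Welch-style t reference.
    """
    (ba, sa), (bb, sb) = a, b
    if sa <= 0 or sb <= 0:
        raise ValidationError("comparison requires positive SEs")
    z = (ba - bb) / np.sqrt(sa**2 + sb**2)
    if df is not None:
        return float(2.0 * stats.t.sf(abs(z), df))
    return float(2.0 * stats.norm.sf(abs(z)))


def evaluate_replication(
    primary: CohortResult | MREstimate,
    meta: MREstimate,
    prior_sign: int,
    p1_threshold: float = 1.1e-5,
    p2_threshold: float = 0.025,
) -> ReplicationVerdict:
    """Apply the four pre-registered replication criteria.

    ``primary`` is the single-cohort analysis judged against ``p1_threshold``
    (criteria 1a/1b); ``meta`` is the meta-analysis of the remaining cohorts
    judged against ``p2_threshold`` (criteria 2a/2b).  ``prior_sign`` is the
    sign (+1/-1) of the effect in the original discovery analysis.
    """
    if prior_sign not in (1, -1):
        raise ValidationError("prior_sign must be +1 or -1")
    if not (0 < p1_threshold < 1 and 0 < p2_threshold < 1):
        raise ValidationError("thresholds must lie in (0,1)")
    est1 = primary.estimate if isinstance(primary, CohortResult) else primary
    for name, est in (("primary", est1), ("meta", meta)):
        if est.beta == 0:
            raise ValidationError(f"{name} beta is exactly zero: sign undefined")
    verdict = ReplicationVerdict(
        criterion_1a=bool(np.sign(est1.beta) == prior_sign),
        criterion_1b=bool(est1.pvalue < p1_threshold),
        criterion_2a=bool(np.sign(meta.beta) == prior_sign),
        criterion_2b=bool(meta.pvalue < p2_threshold),
        observed={
            "primary_beta": est1.beta,
            "primary_p": est1.pvalue,
            "meta_beta": meta.beta,
            "meta_p": meta.pvalue,
        },
        thresholds={"p1": p1_threshold, "p2": p2_threshold},
    )
    return verdict
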