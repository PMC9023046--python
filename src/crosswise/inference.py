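"""Model-fit and model-comparison statistics for crosswise designs.

All tests are likelihood-ratio tests between nested binomial models,
using the asymptotically chi-square distributed statistic
G^2 = 2 * (l_general - l_restricted).  The ECWM fit test exploits the one
degree of freedom gained by running two crosswise groups with distinct
randomization probabilities; technique comparisons equate a crosswise
prevalence parameter with a direct-questioning proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import (
    ArmCounts,
    CrosswiseError,
    RandomizationDesign,
    ecwm_pooled_mle,
    loglik_arm,
    maximize_common_pi,
    saturated_loglik,
)

logger = logging.getLogger("crosswise")

#: Default significance threshold for fit and comparison tests.
ALPHA_DEFAULT = 0.05

#: Negative G^2 beyond this is an error; within it, optimizer noise clamped to 0.
_G2_NUMERICAL_SLACK = 1e-9

FitKind = Literal["ecwm_fit", "technique_comparison", "bound_comparison", "contingency"]


@dataclass(frozen=True)
class FitResult:
    """A G^2 or delta-G^2 statistic with its degrees of freedom and p-value."""

    g2: float
    df: int
    p_value: float
    kind: FitKind

    def significant(self, alpha: float = ALPHA_DEFAULT) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square test of independence with Cramer's V effect size."""

    chi2: float
    df: int
    p_value: float
    cramers_v: float


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < -_G2_NUMERICAL_SLACK:
        raise CrosswiseError(f"chi-square statistic must be nonnegative, got {x}")
    return float(stats.chi2.sf(max(x, 0.0), df))


def _clamp_g2(g2: float) -> float:
    if g2 < -_G2_NUMERICAL_SLACK:
        raise CrosswiseError(f"negative G^2 beyond numerical slack: {g2}")
    if g2 < 0.0:
        logger.debug("clamping optimizer-noise G^2 %.3e to 0", g2)
        return 0.0
    return g2


def ecwm_fit_test(
    arm1: ArmCounts,
    d1: RandomizationDesign,
    arm2: ArmCounts,
    d2: RandomizationDesign,
) -> FitResult:
    """One-degree-of-freedom fit test of the equality-constrained ECWM.

    Compares the saturated model (each arm's both/none probability fixed at
    its observed frequency) against the model in which a single prevalence
    parameter generates both arms through their respective tree links:

        G^2 = 2 * (l_saturated - l_pooled),  df = 1.

    A significant G^2 indicates that the two group estimates disagree — the
    signature of a systematic answer bias (e.g. a preference for the
    "exactly one" option), which a single-group crosswise design cannot
    detect.
    """
    l_sat = saturated_loglik(arm1) + saturated_loglik(arm2)
    _, l_pooled = maximize_common_pi(((arm1, d1), (arm2, d2)))
    g2 = _clamp_g2(2.0 * (l_sat - l_pooled))
    return FitResult(g2=g2, df=1, p_value=chi2_upper_tail(g2, 1), kind="ecwm_fit")


def compare_techniques(
    ecwm_arms: Sequence[Tuple[ArmCounts, RandomizationDesign]],
    dq_arm: ArmCounts,
) -> FitResult:
    """Likelihood-ratio comparison of a crosswise estimate with the DQ estimate.

    Baseline model: one prevalence parameter shared by the ECWM arm(s)
    (their pooled MLE; for a single arm, its own MLE) plus a free DQ
    proportion.  Restricted model: a single prevalence parameter across
    all arms, found numerically.  Then

        delta-G^2 = 2 * (l_baseline - l_restricted),  df = 1.

    With two ECWM arms the result is a ``technique_comparison`` (pooled
    estimate vs DQ); with one arm it is a ``bound_comparison``, used when
    ECWM misfit makes the two group estimates lower/upper bounds that are
    compared to DQ separately.
    """
    if not 1 <= len(ecwm_arms) <= 2:
        raise CrosswiseError("compare_techniques needs one or two ECWM arms")
    if len(ecwm_arms) == 2 and ecwm_arms[0] == ecwm_arms[1]:
        raise CrosswiseError("the same ECWM arm was supplied twice")
    if dq_arm.arm_kind != "DQ":
        raise CrosswiseError("dq_arm must have arm_kind='DQ'")

    if len(ecwm_arms) == 2:
        (a1, d1), (a2, d2) = ecwm_arms
        est = ecwm_pooled_mle(a1, d1, a2, d2)
        l_ecwm = loglik_arm(est.pi_hat, a1, d1) + loglik_arm(est.pi_hat, a2, d2)
        kind: FitKind = "technique_comparison"
    else:
        (a1, d1), = ecwm_arms
        pi_hat, l_ecwm = maximize_common_pi(((a1, d1),))
        kind = "bound_comparison"
    l_baseline = l_ecwm + saturated_loglik(dq_arm)

    all_arms = tuple((a, d) for a, d in ecwm_arms) + ((dq_arm, None),)
    _, l_restricted = maximize_common_pi(all_arms)

    g2 = _clamp_g2(2.0 * (l_baseline - l_restricted))
    return FitResult(g2=g2, df=1, p_value=chi2_upper_tail(g2, 1), kind=kind)


def contingency_chi2(table: Sequence[Sequence[float]]) -> ContingencyResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction is applied.  Cramer's V is
    sqrt(chi2 / (N * (min(r, c) - 1))).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0:
        raise CrosswiseError("table must be a 2-D array of nonnegative counts")
    if t.sum() < 1:
        raise CrosswiseError("table must contain at least one observation")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise CrosswiseError("a zero marginal makes the test undefined")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    n = t.sum()
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    return ContingencyResult(chi2=float(chi2), df=int(df), p_value=float(p), cramers_v=v)


def fit_results_frame(results: List[Tuple[str, FitResult]]):
    """Tabulate labelled fit results (statistic, df, p_value, kind)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"arms": label, "statistic": r.g2, "df": r.df, "p_value": r.p_value, "kind": r.kind}
            for label, r in results
        ]
    )
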