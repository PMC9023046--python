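"""Crosswise-model probability kernel and prevalence estimators.

The Crosswise Model (CWM) is a randomized-response design in which a
sensitive statement is paired with a non-sensitive statement of known
prevalence ``p`` (e.g. "I was born in November or December").  Respondents
answer jointly: "I agree with both or none" versus "I agree with exactly
one".  A respondent's individual answer therefore never reveals their
sensitive status, yet the population prevalence pi of the sensitive
attribute remains estimable because the probability of a "both/none"
answer is

    lambda = pi * p + (1 - pi) * (1 - p)

The Extended Crosswise Model (ECWM) runs two groups with complementary
randomization probabilities p1 and p2 = 1 - p1; equating the prevalence
parameter across the two groups yields one degree of freedom that can be
used to test model fit.

This module provides the forward tree probability, the closed-form
moment estimator (with delta-method standard error), the binomial
log-likelihood for a single arm, the equality-constrained two-arm
maximum-likelihood estimator (Fisher-information standard error), and a
count-reconstruction helper that inverts the estimator to recover the
integer "both/none" count behind a printed (rounded) percentage.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

from scipy.optimize import minimize_scalar

logger = logging.getLogger("crosswise")

#: Absolute tolerance of the bounded scalar optimization over pi in [0, 1].
MLE_XATOL = 1e-12

#: A reconstructed count whose pre-rounding residual exceeds this is flagged:
#: the printed estimate and arm size are then inconsistent at 2-decimal
#: precision.
RECONSTRUCTION_RESIDUAL_TOL = 0.2

#: Distance from {0, 1} below which a maximum-likelihood estimate is treated
#: as lying on the boundary of the parameter space.
BOUNDARY_EPS = 1e-6

ArmKind = Literal["ECWM", "DQ"]
EstimateMethod = Literal["DQ", "CWM_closed_form", "ECWM_pooled_ML"]


class CrosswiseError(ValueError):
    """Base class for input-validation errors raised by this package."""


class UndefinedEstimatorError(CrosswiseError):
    """Raised when p = 1/2, where the crosswise estimator is undefined."""


class EmptyArmError(CrosswiseError):
    """Raised when an arm contains no respondents."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomizationDesign:
    """Randomization probability of one crosswise group.

    Parameters
    ----------
    p
        Known prevalence of the non-sensitive statement, in (0, 1) and
        different from 1/2 (the estimator is undefined at p = 1/2).
    label
        Free-text tag, e.g. ``"p1"`` or ``"p2"``.
    """

    p: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise CrosswiseError(f"randomization probability must lie in (0,1), got {self.p}")
        if self.p == 0.5:
            raise UndefinedEstimatorError(
                "p = 0.5 makes the crosswise estimator undefined (zero slope)"
            )


@dataclass(frozen=True)
class ArmCounts:
    """Aggregate answers of one experimental arm.

    ``n_match`` is the number of "both/none" answers in an ECWM arm, or the
    number of "agree" answers in a direct-questioning (DQ) arm; ``n_total``
    is the arm size.
    """

    n_match: int
    n_total: int
    arm_kind: ArmKind = "ECWM"

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise EmptyArmError(f"arm size must be >= 1, got {self.n_total}")
        if not 0 <= self.n_match <= self.n_total:
            raise CrosswiseError(
                f"n_match must lie in [0, n_total], got {self.n_match}/{self.n_total}"
            )
        if self.arm_kind not in ("ECWM", "DQ"):
            raise CrosswiseError(f"arm_kind must be 'ECWM' or 'DQ', got {self.arm_kind!r}")

    @property
    def frequency(self) -> float:
        """Observed match frequency n_match / n_total."""
        return self.n_match / self.n_total


@dataclass(frozen=True)
class ReconstructedArm(ArmCounts):
    """ArmCounts recovered from a printed estimate, with rounding residual."""

    residual: float = 0.0


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence point estimate with its standard error.

    ``pi_hat`` may fall outside [0, 1] for the raw closed-form crosswise
    estimator (``out_of_range`` is then set); the pooled ML estimate is
    constrained to [0, 1] and ``at_boundary`` flags estimates pinned at 0
    or 1, where the symmetric Fisher SE is only a one-sided caveat.
    """

    pi_hat: float
    se: float
    n_effective: int
    method: EstimateMethod
    arms: Tuple[Tuple[ArmCounts, Optional[RandomizationDesign]], ...] = field(default=())
    out_of_range: bool = False
    at_boundary: bool = False


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def lambda_from_pi(pi: float, design: RandomizationDesign) -> float:
    """Probability of a "both/none" answer given prevalence ``pi``.

    Follows the crosswise processing tree: a carrier matches the
    non-sensitive statement with probability p, a non-carrier with
    probability 1 - p, hence ``lambda = pi*p + (1-pi)*(1-p)`` — linear in
    pi with slope ``2p - 1``.
    """
    if not 0.0 <= pi <= 1.0:
        raise CrosswiseError(f"pi must lie in [0,1], got {pi}")
    p = design.p
    return pi * p + (1.0 - pi) * (1.0 - p)


def _lam_unchecked(pi: float, p: float) -> float:
    return pi * p + (1.0 - pi) * (1.0 - p)


# ---------------------------------------------------------------------------
# Closed-form estimators
# ---------------------------------------------------------------------------


def cwm_estimate(arm: ArmCounts, design: RandomizationDesign) -> PrevalenceEstimate:
    """Closed-form crosswise estimator for a single ECWM arm.

    Inverts the linear tree probability at the observed "both/none"
    frequency lambda_hat = n'/n:

        pi_hat = (lambda_hat + p - 1) / (2p - 1)

    The raw estimate is deliberately *not* clamped to [0, 1]: out-of-range
    values are diagnostic (they occur when the observed frequency is
    incompatible with any prevalence under the model) and are flagged via
    ``out_of_range``.  The standard error is the delta-method transform of
    the binomial SE of lambda_hat:  sqrt(lam(1-lam)/n) / |2p - 1|.
    """
    if arm.arm_kind != "ECWM":
        raise CrosswiseError("cwm_estimate expects an ECWM arm")
    lam_hat = arm.frequency
    slope = 2.0 * design.p - 1.0
    pi_hat = (lam_hat + design.p - 1.0) / slope
    se = math.sqrt(lam_hat * (1.0 - lam_hat) / arm.n_total) / abs(slope)
    out = not 0.0 <= pi_hat <= 1.0
    if out:
        logger.warning(
            "closed-form estimate %.4f outside [0,1] (n'=%d, n=%d, p=%.3f)",
            pi_hat, arm.n_match, arm.n_total, design.p,
        )
    return PrevalenceEstimate(
        pi_hat=pi_hat,
        se=se,
        n_effective=arm.n_total,
        method="CWM_closed_form",
        arms=((arm, design),),
        out_of_range=out,
    )


def dq_estimate(arm: ArmCounts) -> PrevalenceEstimate:
    """Binomial proportion estimate for a direct-questioning arm."""
    if arm.arm_kind != "DQ":
        raise CrosswiseError("dq_estimate expects a DQ arm")
    pi_hat = arm.frequency
    se = math.sqrt(pi_hat * (1.0 - pi_hat) / arm.n_total)
    return PrevalenceEstimate(
        pi_hat=pi_hat,
        se=se,
        n_effective=arm.n_total,
        method="DQ",
        arms=((arm, None),),
    )


# ---------------------------------------------------------------------------
# Count reconstruction
# ---------------------------------------------------------------------------


def reconstruct_counts(
    pi_hat: float,
    design: Optional[RandomizationDesign],
    n_total: int,
) -> ReconstructedArm:
    """Recover the integer answer count behind a printed prevalence estimate.

    Published crosswise studies typically print prevalence estimates (to a
    couple of decimals) and arm sizes, but not the underlying answer
    frequencies.  Because the estimator is a strictly monotone function of
    the count, the count is exactly recoverable: push the printed estimate
    forward through the tree (``lambda = lambda_from_pi(pi_hat, p)`` for an
    ECWM arm, the identity for a DQ arm, ``design=None``) and round
    ``n_total * lambda`` to the nearest integer.

    The pre-rounding residual ``|n_total*lambda - n_match|`` is recorded on
    the returned arm; a residual above 0.2 triggers a warning — the printed
    estimate and arm size are then mutually inconsistent at the printed
    precision.
    """
    if n_total < 1:
        raise EmptyArmError(f"arm size must be >= 1, got {n_total}")
    if design is None:
        if not 0.0 <= pi_hat <= 1.0:
            raise CrosswiseError("a DQ proportion must lie in [0,1]")
        lam = pi_hat
        kind: ArmKind = "DQ"
    else:
        lam = lambda_from_pi(pi_hat, design)
        kind = "ECWM"
    target = n_total * lam
    n_match = int(round(target))
    n_match = min(max(n_match, 0), n_total)
    residual = abs(target - n_match)
    if residual > RECONSTRUCTION_RESIDUAL_TOL:
        warnings.warn(
            f"reconstruction residual {residual:.3f} > {RECONSTRUCTION_RESIDUAL_TOL}: "
            f"printed estimate {pi_hat} and n={n_total} are inconsistent",
            stacklevel=2,
        )
    return ReconstructedArm(n_match=n_match, n_total=n_total, arm_kind=kind, residual=residual)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def loglik_arm(
    pi: float,
    arm: ArmCounts,
    design: Optional[RandomizationDesign] = None,
) -> float:
    """Binomial log-likelihood kernel of one arm at prevalence ``pi``.

    Uses the ECWM tree link for an ECWM arm (``design`` given) and the
    identity link for a DQ arm (``design=None``):

        n' * ln(lambda) + (n - n') * ln(1 - lambda)

    with the 0*ln(0) = 0 convention.  A boundary lambda with interior
    counts returns ``-inf`` rather than raising.
    """
    lam = pi if design is None else lambda_from_pi(pi, design)
    return _loglik_lam(arm.n_match, arm.n_total, lam)


def _loglik_lam(n_match: int, n_total: int, lam: float) -> float:
    # 0*ln 0 = 0 convention; boundary lambda with interior counts -> -inf
    if lam <= 0.0:
        return 0.0 if n_match == 0 else -math.inf
    if lam >= 1.0:
        return 0.0 if n_match == n_total else -math.inf
    return n_match * math.log(lam) + (n_total - n_match) * math.log(1.0 - lam)


def saturated_loglik(arm: ArmCounts) -> float:
    """Log-likelihood of one arm with lambda fixed at its observed frequency."""
    return _loglik_lam(arm.n_match, arm.n_total, arm.frequency)


# ---------------------------------------------------------------------------
# Pooled maximum likelihood
# ---------------------------------------------------------------------------


def _pooled_loglik(pi: float, arms: Sequence[Tuple[ArmCounts, Optional[RandomizationDesign]]]) -> float:
    total = 0.0
    for arm, design in arms:
        lam = pi if design is None else _lam_unchecked(pi, design.p)
        total += _loglik_lam(arm.n_match, arm.n_total, lam)
    return total


def maximize_common_pi(
    arms: Sequence[Tuple[ArmCounts, Optional[RandomizationDesign]]],
) -> Tuple[float, float]:
    """Maximize the joint log-likelihood of several arms over a common pi.

    Each arm contributes a binomial term through its own link (ECWM tree or
    DQ identity).  Bounded Brent search on [0, 1] with absolute tolerance
    ``MLE_XATOL``; deterministic.  Returns ``(pi_hat, loglik_at_max)``.
    """
    if not arms:
        raise CrosswiseError("need at least one arm")
    res = minimize_scalar(
        lambda pi: -_pooled_loglik(pi, arms),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": MLE_XATOL},
    )
    pi_hat = float(res.x)
    # the bounded optimizer never quite reaches the bounds; snap if the
    # boundary value is at least as good
    for edge in (0.0, 1.0):
        if _pooled_loglik(edge, arms) >= -res.fun:
            pi_hat = edge
    return pi_hat, _pooled_loglik(pi_hat, arms)


def ecwm_pooled_mle(
    arm1: ArmCounts,
    d1: RandomizationDesign,
    arm2: ArmCounts,
    d2: RandomizationDesign,
) -> PrevalenceEstimate:
    """Equality-constrained two-group ECWM maximum-likelihood estimate.

    The prevalence parameters of the two ECWM groups are pooled into a
    single pi and the joint two-arm binomial likelihood is maximized over
    pi in [0, 1].  The standard error is the inverse square root of the
    observed Fisher information at the MLE,

        I(pi) = sum_g n_g (2 p_g - 1)^2 / (lambda_g (1 - lambda_g)),

    which for a single arm reduces to the delta-method SE of the
    closed-form estimator.  An MLE pinned at 0 or 1 is flagged
    (``at_boundary``): the symmetric SE is then only a one-sided caveat.
    """
    if d1.p == d2.p:
        logger.warning("both arms share p=%.3f; the design is not identified as ECWM", d1.p)
    arms = ((arm1, d1), (arm2, d2))
    pi_hat, _ = maximize_common_pi(arms)
    at_boundary = pi_hat < BOUNDARY_EPS or pi_hat > 1.0 - BOUNDARY_EPS
    info = 0.0
    for arm, design in arms:
        lam = _lam_unchecked(pi_hat, design.p)
        lam = min(max(lam, 1e-12), 1.0 - 1e-12)
        info += arm.n_total * (2.0 * design.p - 1.0) ** 2 / (lam * (1.0 - lam))
    se = info ** -0.5
    if at_boundary:
        logger.warning("pooled MLE at boundary (pi_hat=%.6f); SE is a one-sided caveat", pi_hat)
    return PrevalenceEstimate(
        pi_hat=pi_hat,
        se=se,
        n_effective=arm1.n_total + arm2.n_total,
        method="ECWM_pooled_ML",
        arms=arms,
        at_boundary=at_boundary,
    )
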