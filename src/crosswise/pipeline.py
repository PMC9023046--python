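"""Study-level orchestration: the 2x2 validation framework and reproduction.

The weak-validation logic implemented here crosses the direction of social
desirability (undesirable vs. desirable attribute) with the attribute's
prevalence (below vs. above 50%).  Successful control of social
desirability predicts crosswise estimates above DQ for undesirable
attributes ("more is better") and below DQ for desirable ones ("less is
better"), regardless of prevalence.  Random responding instead pulls
crosswise estimates toward 50%, predicting crosswise > DQ for
low-prevalence and crosswise < DQ for high-prevalence attributes,
regardless of desirability.  The two accounts disagree precisely in the
two diagnostic cells — undesirable/high-prevalence and
desirable/low-prevalence — which is what makes the full factorial design
able to separate them.

A packaged fixture carries the printed quantities of one large German
online-panel ECWM validation study (eight attributes, two per cell,
p1 = .158 / p2 = .842 from official birth-month statistics), so every
inferential statistic can be recomputed from scratch: the integer answer
counts are recovered from the printed estimates by inverting the
estimator, and all estimates, standard errors and likelihood-ratio
statistics are then recomputed from those counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ArmCounts,
    CrosswiseError,
    RandomizationDesign,
    cwm_estimate,
    dq_estimate,
    ecwm_pooled_mle,
    reconstruct_counts,
)
from .inference import (
    ALPHA_DEFAULT,
    ContingencyResult,
    FitResult,
    compare_techniques,
    contingency_chi2,
    ecwm_fit_test,
)

# ---------------------------------------------------------------------------
# Packaged study fixture (printed quantities; percentages as printed)
# ---------------------------------------------------------------------------

P1 = RandomizationDesign(0.158, "p1")
P2 = RandomizationDesign(0.842, "p2")


@dataclass(frozen=True)
class AttributeFixture:
    """Printed quantities for one sensitive attribute (all percentages)."""

    attribute: str
    statement: str
    desirability: str       # 'undesirable' | 'desirable'
    prevalence_level: str   # 'low' | 'high'
    pi1: float
    se1: float
    n1: int
    pi2: float
    se2: float
    n2: int
    fit_g2: float
    dq: float
    dq_se: float
    n_dq: int
    pooled: float
    pooled_se: float
    delta_g2: float
    lower_bound_g2: Optional[float] = None  # p2-group estimate vs DQ
    upper_bound_g2: Optional[float] = None  # p1-group estimate vs DQ


STUDY_ATTRIBUTES: Tuple[AttributeFixture, ...] = (
    AttributeFixture("borrowed_item", "I have not returned a borrowed item.",
                     "undesirable", "low", 49.46, 3.15, 538, 46.58, 3.16, 535,
                     0.42, 39.27, 2.09, 545, 48.02, 2.23, 8.14),
    AttributeFixture("trash_disposal", "I have illegally disposed of trash.",
                     "undesirable", "low", 26.63, 2.99, 538, 28.55, 3.02, 535,
                     0.20, 21.47, 1.76, 545, 27.59, 2.13, 4.88),
    AttributeFixture("lying", "I sometimes lie.",
                     "undesirable", "high", 77.70, 2.91, 541, 57.07, 3.14, 538,
                     22.88, 71.43, 1.92, 553, 67.41, 2.16, 1.92,
                     lower_bound_g2=15.33, upper_bound_g2=3.19),
    AttributeFixture("excess_change", "I have kept change that was mistakenly given back to me in excess.",
                     "undesirable", "high", 70.13, 3.02, 541, 57.34, 3.14, 538,
                     8.58, 58.77, 2.10, 553, 63.75, 2.19, 2.71,
                     lower_bound_g2=0.14, upper_bound_g2=9.39),
    AttributeFixture("prevent_violence", "I have actively intervened to prevent violence against women or children.",
                     "desirable", "low", 27.60, 2.98, 545, 32.37, 3.07, 535,
                     1.25, 40.26, 2.09, 549, 29.97, 2.14, 11.84),
    AttributeFixture("volunteering", "I volunteer in the social sector.",
                     "desirable", "low", 25.99, 2.96, 545, 25.00, 2.97, 535,
                     0.06, 32.79, 2.01, 549, 25.50, 2.10, 6.35),
    AttributeFixture("vote", "I cast my vote in the last federal election.",
                     "desirable", "high", 86.48, 2.72, 543, 66.24, 3.07, 540,
                     24.00, 83.95, 1.58, 542, 76.39, 2.07, 8.32,
                     lower_bound_g2=27.14, upper_bound_g2=0.64),
    AttributeFixture("checkups", "I go for regular medical checkups.",
                     "desirable", "high", 63.60, 3.09, 543, 55.41, 3.14, 540,
                     3.45, 70.30, 1.96, 542, 59.52, 2.20, 13.13),
)

#: Dropout 2x2 table (rows: DQ, ECWM; cols: dropouts, completers),
#: reconstructed from the initial N = 7172, 668 dropouts, and the per-arm
#: dropout rates 1.93% (DQ) / 12.65% (ECWM).
DROPOUT_TABLE = ((43, 2189), (625, 4315))

#: Self-reported random responding: fraction of the final sample retained
#: when excluding everyone scoring >= 2 on the 1-7 "I just randomly ticked
#: one of the answers" item (n = 5619 of 6504).
EXCLUSION_RETAINED_FRACTION = 0.8639
N_FINAL_SAMPLE = 6504


@dataclass(frozen=True)
class StudyFixture:
    attributes: Tuple[AttributeFixture, ...] = STUDY_ATTRIBUTES
    p1: RandomizationDesign = P1
    p2: RandomizationDesign = P2
    dropout_table: Tuple[Tuple[int, int], Tuple[int, int]] = DROPOUT_TABLE


STUDY_FIXTURE = StudyFixture()


# ---------------------------------------------------------------------------
# Pattern classification (the 2x2 disentangling grid)
# ---------------------------------------------------------------------------

DIAGNOSTIC_CELLS = {("undesirable", "high"), ("desirable", "low")}


@dataclass(frozen=True)
class AttributeComparison:
    """One crosswise-vs-DQ comparison feeding the pattern classifier."""

    attribute: str
    desirability: str
    prevalence_level: str
    pi_ecwm: float
    pi_dq: float
    p_value: float


@dataclass(frozen=True)
class CellVerdict:
    cell: Tuple[str, str]
    attribute: str
    direction: int  # sign of (pi_ecwm - pi_dq)
    significant: bool
    consistent_with: frozenset


def _expected_direction(account: str, desirability: str, prevalence_level: str) -> int:
    if account == "sd_control":
        return 1 if desirability == "undesirable" else -1
    if account == "random_responding":
        return 1 if prevalence_level == "low" else -1
    raise CrosswiseError(f"unknown account {account!r}")


def classify_pattern(
    comparisons: Sequence[AttributeComparison],
    alpha: float = ALPHA_DEFAULT,
) -> Tuple[List[CellVerdict], Dict[str, str]]:
    """Map crosswise-vs-DQ comparisons onto the 2x2 expectation grid.

    For each comparison, ``consistent_with`` collects the accounts
    (``sd_control``, ``random_responding``) whose predicted direction of
    (crosswise - DQ) matches the observed one.  The overall verdict is the
    account consistent with strictly more *significant* comparisons in
    the two diagnostic cells (undesirable/high, desirable/low); ties give
    ``"mixed"``.  Because the non-diagnostic cells cannot discriminate,
    an all-cells tally is also reported.
    """
    if not comparisons:
        raise CrosswiseError("no comparisons supplied")
    cells_present = {(c.desirability, c.prevalence_level) for c in comparisons}
    if not cells_present & DIAGNOSTIC_CELLS:
        raise CrosswiseError(
            "need at least one diagnostic cell (undesirable/high or desirable/low)"
        )
    verdicts: List[CellVerdict] = []
    for c in comparisons:
        direction = int(np.sign(c.pi_ecwm - c.pi_dq))
        consistent = frozenset(
            a for a in ("sd_control", "random_responding")
            if direction != 0 and direction == _expected_direction(a, c.desirability, c.prevalence_level)
        )
        verdicts.append(CellVerdict(
            cell=(c.desirability, c.prevalence_level),
            attribute=c.attribute,
            direction=direction,
            significant=c.p_value < alpha,
            consistent_with=consistent,
        ))

    def tally(subset: List[CellVerdict]) -> str:
        counts = {a: sum(1 for v in subset if v.significant and a in v.consistent_with)
                  for a in ("sd_control", "random_responding")}
        if counts["sd_control"] > counts["random_responding"]:
            return "sd_control"
        if counts["random_responding"] > counts["sd_control"]:
            return "random_responding"
        return "mixed"

    overall = {
        "diagnostic": tally([v for v in verdicts if v.cell in DIAGNOSTIC_CELLS]),
        "all_cells": tally(verdicts),
    }
    return verdicts, overall


# ---------------------------------------------------------------------------
# Reproduction of the packaged study
# ---------------------------------------------------------------------------


def reproduce_attribute(
    attr: AttributeFixture,
    p1: RandomizationDesign = P1,
    p2: RandomizationDesign = P2,
    alpha: float = ALPHA_DEFAULT,
) -> Dict[str, object]:
    """Recompute every statistic for one attribute from reconstructed counts."""
    arm1 = reconstruct_counts(attr.pi1 / 100.0, p1, attr.n1)
    arm2 = reconstruct_counts(attr.pi2 / 100.0, p2, attr.n2)
    dq_arm = reconstruct_counts(attr.dq / 100.0, None, attr.n_dq)
    est1 = cwm_estimate(arm1, p1)
    est2 = cwm_estimate(arm2, p2)
    est_dq = dq_estimate(dq_arm)
    pooled = ecwm_pooled_mle(arm1, p1, arm2, p2)
    fit = ecwm_fit_test(arm1, p1, arm2, p2)
    comparison = compare_techniques([(arm1, p1), (arm2, p2)], dq_arm)
    out: Dict[str, object] = {
        "attribute": attr.attribute,
        "arms": {"p1": arm1, "p2": arm2, "dq": dq_arm},
        "max_residual": max(arm1.residual, arm2.residual, dq_arm.residual),
        "pi1": est1, "pi2": est2, "dq": est_dq, "pooled": pooled,
        "fit": fit, "comparison": comparison,
        "lower_bound": None, "upper_bound": None,
    }
    if fit.p_value < alpha:
        # group estimates become lower/upper bounds, each compared to DQ
        out["lower_bound"] = compare_techniques([(arm2, p2)], dq_arm)
        out["upper_bound"] = compare_techniques([(arm1, p1)], dq_arm)
    return out


def reproduce_results(
    fixture: StudyFixture = STUDY_FIXTURE,
    alpha: float = ALPHA_DEFAULT,
    attributes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Side-by-side table of recomputed vs printed study statistics.

    Returns a tidy frame with one row per (attribute, quantity):
    per-group estimates and SEs, the pooled estimate and SE, the fit G^2,
    the pooled-vs-DQ delta-G^2 and — for attributes whose fit test
    rejects — the two bound comparisons.  Percentages are on the printed
    percent scale; ``deviation`` is recomputed minus printed.
    """
    rows = []
    for attr in fixture.attributes:
        if attributes is not None and attr.attribute not in attributes:
            continue
        r = reproduce_attribute(attr, fixture.p1, fixture.p2, alpha)
        flagged = r["max_residual"] > 0.2
        quantities = [
            ("pi1_pct", r["pi1"].pi_hat * 100, attr.pi1),
            ("se1_pct", r["pi1"].se * 100, attr.se1),
            ("pi2_pct", r["pi2"].pi_hat * 100, attr.pi2),
            ("se2_pct", r["pi2"].se * 100, attr.se2),
            ("dq_pct", r["dq"].pi_hat * 100, attr.dq),
            ("dq_se_pct", r["dq"].se * 100, attr.dq_se),
            ("pooled_pct", r["pooled"].pi_hat * 100, attr.pooled),
            ("pooled_se_pct", r["pooled"].se * 100, attr.pooled_se),
            ("fit_g2", r["fit"].g2, attr.fit_g2),
            ("delta_g2", r["comparison"].g2, attr.delta_g2),
        ]
        if r["lower_bound"] is not None:
            quantities.append(("lower_bound_g2", r["lower_bound"].g2, attr.lower_bound_g2))
            quantities.append(("upper_bound_g2", r["upper_bound"].g2, attr.upper_bound_g2))
        for name, recomputed, printed in quantities:
            rows.append({
                "attribute": attr.attribute,
                "quantity": name,
                "recomputed": recomputed,
                "printed": printed,
                "deviation": None if printed is None else recomputed - printed,
                "flagged": flagged,
            })
    return pd.DataFrame(rows)


def study_comparisons(
    fixture: StudyFixture = STUDY_FIXTURE,
    alpha: float = ALPHA_DEFAULT,
) -> List[AttributeComparison]:
    """Recomputed crosswise-vs-DQ comparisons ready for the classifier."""
    out = []
    for attr in fixture.attributes:
        r = reproduce_attribute(attr, fixture.p1, fixture.p2, alpha)
        out.append(AttributeComparison(
            attribute=attr.attribute,
            desirability=attr.desirability,
            prevalence_level=attr.prevalence_level,
            pi_ecwm=r["pooled"].pi_hat,
            pi_dq=r["dq"].pi_hat,
            p_value=r["comparison"].p_value,
        ))
    return out


def dropout_contingency(fixture: StudyFixture = STUDY_FIXTURE) -> ContingencyResult:
    """Chi-square test of dropout rate by questioning technique."""
    return contingency_chi2(fixture.dropout_table)


# ---------------------------------------------------------------------------
# Exploratory exclusion filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionRule:
    """Exclude self-admitted random responders above a Likert threshold.

    Respondents rate "I just randomly ticked one of the answers" on a 1-7
    scale; everyone scoring at or above ``likert_threshold`` is excluded
    (i.e. scores strictly below the threshold are retained).
    """

    likert_threshold: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.likert_threshold <= 7:
            raise CrosswiseError(f"likert_threshold must lie in [1,7], got {self.likert_threshold}")


def apply_exclusion(
    records: pd.DataFrame,
    rule: ExclusionRule,
    scores: Optional[Sequence[int]] = None,
    column: str = "random_likert",
) -> Tuple[pd.DataFrame, float]:
    """Filter respondent records on the random-responding self-report.

    ``scores`` (one 1-7 value per record) may be passed separately or as a
    column of ``records``.  Returns the retained records and the retained
    fraction.
    """
    if scores is None:
        if column not in records.columns:
            raise CrosswiseError(f"records lack a {column!r} column and no scores were given")
        scores = records[column].to_numpy()
    s = np.asarray(scores)
    if len(s) != len(records):
        raise CrosswiseError("scores and records length mismatch")
    if len(s) == 0:
        raise CrosswiseError("no records supplied")
    if s.min() < 1 or s.max() > 7:
        raise CrosswiseError("Likert scores must lie in 1..7")
    keep = s < rule.likert_threshold
    return records.loc[keep].reset_index(drop=True), float(keep.mean())
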