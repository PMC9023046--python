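"""Respondent-level simulator for direct-questioning and crosswise arms.

Generates individual survey records under a configurable behavioral
mixture applied in a fixed order:

1. latent truth: carrier status drawn Bernoulli(pi_true);
2. social-desirability misreporting: a respondent whose truthful answer
   is socially unfavorable (a carrier of an undesirable attribute, a
   non-carrier of a desirable one) flips toward the favorable answer with
   probability ``sd_rate_dq`` (DQ) or ``sd_rate_ecwm`` (crosswise);
3. random responding: with probability ``gamma_random`` the final answer
   is replaced by a fair coin;
4. systematic option preference (crosswise only): with probability
   ``beta_exactly_one`` the respondent picks "exactly one" regardless of
   truth.

Under this mixture the expected crosswise estimate obeys the classic
bias-toward-50% law  E[pi_hat] = (1 - gamma) * pi + gamma / 2  when only
random responding is active, and a nonzero beta pushes the two group
estimates apart (up in the low-p group, down in the high-p group),
producing exactly the misfit signature the two-group design detects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Literal, Optional, Tuple

import numpy as np
import pandas as pd

from .core import ArmCounts, CrosswiseError, RandomizationDesign, lambda_from_pi
from .inference import compare_techniques

Desirability = Literal["undesirable", "desirable"]
ArmName = Literal["DQ", "ECWM_p1", "ECWM_p2"]

RECORD_COLUMNS = ["id", "cell_desirability", "cell_prevalence", "arm", "answer"]
LATENT_COLUMNS = ["carrier", "nonsensitive_true"]


@dataclass(frozen=True)
class BehaviorParams:
    """Answering-behavior mixture of one experimental cell.

    ``gamma_random`` applies to every arm by default; random responding is
    plausibly format-specific (the crosswise format carries a higher
    comprehension burden than a direct question), so ``gamma_random_dq``
    can override the DQ arm's rate — e.g. set it to 0 to confine random
    responding to the crosswise arms.
    """

    pi_true: float
    desirability: Desirability = "undesirable"
    sd_rate_dq: float = 0.0
    sd_rate_ecwm: float = 0.0
    gamma_random: float = 0.0
    beta_exactly_one: float = 0.0
    gamma_random_dq: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("pi_true", "sd_rate_dq", "sd_rate_ecwm", "gamma_random", "beta_exactly_one"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CrosswiseError(f"{name} must lie in [0,1], got {v}")
        if self.gamma_random_dq is not None and not 0.0 <= self.gamma_random_dq <= 1.0:
            raise CrosswiseError(f"gamma_random_dq must lie in [0,1], got {self.gamma_random_dq}")
        if self.gamma_random + self.beta_exactly_one > 1.0:
            raise CrosswiseError("gamma_random + beta_exactly_one must not exceed 1")
        if self.desirability not in ("undesirable", "desirable"):
            raise CrosswiseError(f"unknown desirability {self.desirability!r}")

    @property
    def dq_gamma(self) -> float:
        return self.gamma_random if self.gamma_random_dq is None else self.gamma_random_dq


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate with its binomial error."""

    power: float
    mc_se: float
    n_per_arm: int
    reps: int
    alpha: float
    seed: int


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    if seed is None:
        raise CrosswiseError("a seed (or an explicit rng) is required for reproducibility")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Core samplers (latent arrays)
# ---------------------------------------------------------------------------


def _sample_dq(n: int, params: BehaviorParams, rng: np.random.Generator):
    carrier = rng.random(n) < params.pi_true
    answer = carrier.copy()
    unfavorable = carrier if params.desirability == "undesirable" else ~carrier
    flip = unfavorable & (rng.random(n) < params.sd_rate_dq)
    answer[flip] = params.desirability == "desirable"
    noisy = rng.random(n) < params.dq_gamma
    answer[noisy] = rng.random(noisy.sum()) < 0.5
    return carrier, answer


def _sample_ecwm(n: int, params: BehaviorParams, design: RandomizationDesign,
                 rng: np.random.Generator):
    carrier = rng.random(n) < params.pi_true
    reported = carrier.copy()
    unfavorable = carrier if params.desirability == "undesirable" else ~carrier
    flip = unfavorable & (rng.random(n) < params.sd_rate_ecwm)
    reported[flip] = params.desirability == "desirable"
    nonsensitive = rng.random(n) < design.p
    answer = reported == nonsensitive  # honest "both/none" iff statuses match
    u = rng.random(n)
    noisy = u < params.gamma_random
    answer[noisy] = rng.random(noisy.sum()) < 0.5
    exactly_one = (u >= params.gamma_random) & (u < params.gamma_random + params.beta_exactly_one)
    answer[exactly_one] = False
    return carrier, nonsensitive, answer


def _frame(ids, desirability, prevalence, arm, answer, carrier=None, nonsensitive=None):
    data = {
        "id": ids,
        "cell_desirability": desirability,
        "cell_prevalence": prevalence,
        "arm": arm,
        "answer": answer.astype(int),
    }
    if carrier is not None:
        data["carrier"] = carrier.astype(int)
        data["nonsensitive_true"] = (
            nonsensitive.astype(int) if nonsensitive is not None else pd.NA
        )
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Public simulation operations
# ---------------------------------------------------------------------------


def simulate_dq(
    n: int,
    params: BehaviorParams,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    cell: Tuple[str, str] = ("undesirable", "low"),
    keep_latent: bool = True,
) -> Tuple[pd.DataFrame, ArmCounts]:
    """Simulate one direct-questioning arm.

    Expected agree-rate under the mixture: for an undesirable attribute
    ``(1-gamma)*pi*(1-s) + gamma/2``; for a desirable one
    ``(1-gamma)*(pi + (1-pi)*s) + gamma/2``, with ``s = sd_rate_dq``.
    """
    if n < 1:
        raise CrosswiseError(f"arm size must be >= 1, got {n}")
    gen = _rng(seed, rng)
    carrier, answer = _sample_dq(n, params, gen)
    records = _frame(
        np.arange(n), cell[0], cell[1], "DQ", answer,
        carrier if keep_latent else None, None,
    )
    return records, ArmCounts(int(answer.sum()), n, arm_kind="DQ")


def simulate_ecwm(
    n: int,
    params: BehaviorParams,
    design: RandomizationDesign,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    cell: Tuple[str, str] = ("undesirable", "low"),
    arm_name: str = "ECWM",
    keep_latent: bool = True,
) -> Tuple[pd.DataFrame, ArmCounts]:
    """Simulate one crosswise arm.

    The non-sensitive randomizer (e.g. a birthday statement) is drawn
    independently of carrier status.  Expected "both/none" rate:
    ``(1 - gamma - beta) * lambda(pi_eff) + gamma/2`` where ``pi_eff``
    applies the social-desirability flip to the true prevalence.
    """
    if n < 1:
        raise CrosswiseError(f"arm size must be >= 1, got {n}")
    gen = _rng(seed, rng)
    carrier, nonsensitive, answer = _sample_ecwm(n, params, design, gen)
    records = _frame(
        np.arange(n), cell[0], cell[1], arm_name, answer,
        carrier if keep_latent else None, nonsensitive if keep_latent else None,
    )
    return records, ArmCounts(int(answer.sum()), n, arm_kind="ECWM")


def simulate_design(
    cells: Dict[Tuple[str, str], BehaviorParams],
    arm_sizes: Dict[Tuple[str, str], Dict[str, int]],
    designs: Tuple[RandomizationDesign, RandomizationDesign],
    seed: int,
    *,
    keep_latent: bool = False,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str, str], ArmCounts]]:
    """Simulate a full factorial design (desirability x prevalence x arm).

    ``cells`` maps ``(desirability, prevalence_level)`` to the cell's
    behavior; ``arm_sizes`` maps the same keys to per-arm sizes keyed
    ``"ECWM_p1" | "ECWM_p2" | "DQ"``.  One RNG stream drives the whole
    call, so a fixed seed yields a byte-identical respondent table.
    """
    if not cells:
        raise CrosswiseError("no cells supplied")
    missing = set(cells) - set(arm_sizes)
    if missing:
        raise CrosswiseError(f"missing arm sizes for cells: {sorted(missing)}")
    d1, d2 = designs
    gen = np.random.default_rng(seed)
    frames = []
    counts: Dict[Tuple[str, str, str], ArmCounts] = {}
    next_id = 0
    for key in sorted(cells):
        params = cells[key]
        sizes = arm_sizes[key]
        for arm_name in ("ECWM_p1", "ECWM_p2", "DQ"):
            n = int(sizes[arm_name])
            if arm_name == "DQ":
                recs, arm = simulate_dq(n, params, rng=gen, cell=key, keep_latent=keep_latent)
            else:
                design = d1 if arm_name == "ECWM_p1" else d2
                recs, arm = simulate_ecwm(
                    n, params, design, rng=gen, cell=key,
                    arm_name=arm_name, keep_latent=keep_latent,
                )
            recs = recs.assign(id=np.arange(next_id, next_id + n))
            next_id += n
            frames.append(recs)
            counts[key + (arm_name,)] = arm
    return pd.concat(frames, ignore_index=True), counts


def expected_ecwm_estimate(params: BehaviorParams) -> float:
    """Large-sample limit of the crosswise estimate under the mixture.

    With only random responding active this is the bias-toward-50% law
    ``(1 - gamma) * pi + gamma / 2``; a nonzero ``beta_exactly_one`` adds
    a design-dependent distortion and is not covered by this helper
    (it requires the group's p; see the misfit signature in the docs).
    """
    pi = params.pi_true
    s = params.sd_rate_ecwm
    if params.desirability == "undesirable":
        pi_eff = pi * (1.0 - s)
    else:
        pi_eff = pi + (1.0 - pi) * s
    if params.beta_exactly_one:
        raise CrosswiseError("closed form only valid for beta_exactly_one = 0")
    g = params.gamma_random
    return (1.0 - g) * pi_eff + g / 2.0


def power_simulation(
    dq_regime: BehaviorParams,
    ecwm_regime: BehaviorParams,
    n_dq: int,
    n_ecwm_per_group: int,
    designs: Tuple[RandomizationDesign, RandomizationDesign],
    alpha: float,
    reps: int,
    seed: int,
) -> PowerResult:
    """Monte-Carlo power of the pooled-crosswise-vs-DQ comparison.

    Repeatedly simulates one DQ arm under ``dq_regime`` and two crosswise
    arms under ``ecwm_regime``, runs the likelihood-ratio technique
    comparison, and reports the rejection fraction at ``alpha`` with its
    binomial Monte-Carlo standard error.  When the two regimes imply the
    same expected estimate the result is the type-I error rate
    (approximately ``alpha``), not a defect.
    """
    if reps < 100:
        raise CrosswiseError("use at least 100 replications")
    d1, d2 = designs
    gen = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        _, dq_arm = _counts_only_dq(n_dq, dq_regime, gen)
        _, a1 = _counts_only_ecwm(n_ecwm_per_group, ecwm_regime, d1, gen)
        _, a2 = _counts_only_ecwm(n_ecwm_per_group, ecwm_regime, d2, gen)
        res = compare_techniques([(a1, d1), (a2, d2)], dq_arm)
        rejections += res.p_value < alpha
    power = rejections / reps
    mc_se = float(np.sqrt(power * (1.0 - power) / reps))
    return PowerResult(power=power, mc_se=mc_se, n_per_arm=n_ecwm_per_group,
                       reps=reps, alpha=alpha, seed=seed)


def _counts_only_dq(n, params, gen):
    carrier, answer = _sample_dq(n, params, gen)
    return carrier, ArmCounts(int(answer.sum()), n, arm_kind="DQ")


def _counts_only_ecwm(n, params, design, gen):
    carrier, _, answer = _sample_ecwm(n, params, design, gen)
    return carrier, ArmCounts(int(answer.sum()), n, arm_kind="ECWM")
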